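"""Clonotype calling and clonal-expansion statistics.

A clone is the set of cells sharing an identical rearranged TCR key — the
productive TRB V gene + J gene + CDR3 nucleotide sequence (optionally plus the
analogous TRA key in ``paired`` mode).  A clone is *expanded* when it is
observed in at least two cells; clone size is counted within condition across
all clusters ("global size"), which is what lets the same clone be tracked as
it spreads across phenotypic clusters.

The module computes, per cluster and condition: the number of TCR-bearing
cells, unique clones, the percentage of clonally expanded cells, the mean
clone size, the cross-cluster clone-sharing matrix, and per-clone cluster
occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import ContigRecord

EXPANDED_MIN_SIZE = 2


@dataclass
class CloneAssignment:
    """Barcode -> clone mapping plus the key behind every clone id."""

    barcode_to_clone: dict[str, int]
    clone_keys: dict[int, tuple]
    scope: str  # "global" or "per_condition"
    unassigned: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"barcode": list(self.barcode_to_clone),
             "clone_id": list(self.barcode_to_clone.values())})


def _best_chain(records: list[ContigRecord]) -> ContigRecord | None:
    """Most-supported productive contig: max UMIs, ties to smallest cdr3_nt."""
    productive = [r for r in records if r.productive]
    if not productive:
        return None
    return min(productive, key=lambda r: (-r.umis, r.cdr3_nt))


def call_clonotypes(contigs: list[ContigRecord], mode: str = "trb_only",
                    scope: str = "global",
                    conditions: dict[str, str] | None = None) -> CloneAssignment:
    """Assign each barcode to a clone.

    Per barcode, only productive chains count; with multiple productive TRB
    contigs the one with most UMIs wins (ties broken by lexicographically
    smallest CDR3 nucleotide).  The clone key is (TRB V, J, CDR3nt); in
    ``paired`` mode the TRA key is appended (empty when no productive TRA).
    Barcodes with no productive TRB are left unassigned and reported.

    With ``scope="per_condition"`` the same key in two conditions yields two
    distinct clone ids; ``conditions`` (barcode -> condition) is then required.
    """
    if mode not in ("trb_only", "paired"):
        raise ConfigError(f"unknown clonotype mode {mode!r}")
    if scope not in ("global", "per_condition"):
        raise ConfigError(f"unknown clonotype scope {scope!r}")
    if scope == "per_condition" and conditions is None:
        raise ConfigError("per_condition scope requires a conditions mapping")

    by_barcode: dict[str, list[ContigRecord]] = {}
    for r in contigs:
        by_barcode.setdefault(r.barcode, []).append(r)

    key_to_id: dict[tuple, int] = {}
    barcode_to_clone: dict[str, int] = {}
    unassigned = []
    for bc in by_barcode:
        recs = by_barcode[bc]
        trb = _best_chain([r for r in recs if r.chain == "TRB"])
        if trb is None:
            unassigned.append(bc)
            continue
        key: tuple = (trb.v_gene, trb.j_gene, trb.cdr3_nt)
        if mode == "paired":
            tra = _best_chain([r for r in recs if r.chain == "TRA"])
            key = key + ((tra.v_gene, tra.j_gene, tra.cdr3_nt)
                         if tra else ("", "", ""))
        if scope == "per_condition":
            key = (conditions[bc],) + key
        if key not in key_to_id:
            key_to_id[key] = len(key_to_id)
        barcode_to_clone[bc] = key_to_id[key]
    return CloneAssignment(
        barcode_to_clone=barcode_to_clone,
        clone_keys={v: k for k, v in key_to_id.items()},
        scope=scope, unassigned=unassigned)


def _clone_frame(assignment: CloneAssignment, labels: dict[str, int],
                 conditions: dict[str, str]) -> pd.DataFrame:
    """Long table of (barcode, clone_id, cluster, condition, global_size).

    Only barcodes present in both the assignment and the label map enter the
    statistics; clone size is computed within condition across clusters.
    """
    rows = [(bc, cl, labels[bc], conditions[bc])
            for bc, cl in assignment.barcode_to_clone.items() if bc in labels]
    df = pd.DataFrame(rows, columns=["barcode", "clone_id", "cluster",
                                     "condition"])
    if df.empty:
        return df.assign(global_size=pd.Series(dtype=int))
    sizes = df.groupby(["condition", "clone_id"])["barcode"].transform("size")
    return df.assign(global_size=sizes)


def count_unique_clones(assignment: CloneAssignment,
                        conditions: dict[str, str]) -> pd.Series:
    """Number of distinct clones among TCR-bearing cells, per condition."""
    df = pd.DataFrame(
        [(bc, cl, conditions[bc])
         for bc, cl in assignment.barcode_to_clone.items() if bc in conditions],
        columns=["barcode", "clone_id", "condition"])
    if df.empty:
        return pd.Series(dtype=int, name="n_unique_clones")
    out = df.groupby("condition")["clone_id"].nunique()
    out.name = "n_unique_clones"
    return out


def cluster_clonal_stats(assignment: CloneAssignment, labels: dict[str, int],
                         conditions: dict[str, str],
                         size_scope: str = "global") -> pd.DataFrame:
    """Per (cluster, condition) clonal statistics.

    ``pct_expanded`` = percent of TCR-bearing cells in the cluster whose clone
    has (within-condition) global size >= 2.  ``mean_clone_size`` = mean over
    the unique clones present in the cluster of their within-condition global
    size (``size_scope="within_cluster"`` instead averages the clone's cell
    count inside the cluster).  Clusters with no TCR-bearing cells yield a
    null row with a warning.
    """
    if size_scope not in ("global", "within_cluster"):
        raise ConfigError(f"unknown size_scope {size_scope!r}")
    df = _clone_frame(assignment, labels, conditions)
    all_clusters = sorted(set(labels.values()))
    all_conditions = sorted(set(conditions.values()))
    rows = []
    for cond in all_conditions:
        sub = df[df["condition"] == cond]
        for k in all_clusters:
            cells = sub[sub["cluster"] == k]
            if cells.empty:
                warnings.warn(
                    f"cluster {k} / condition {cond}: no TCR-bearing cells")
                rows.append({"cluster_id": k, "condition": cond,
                             "n_cells_with_tcr": 0, "n_unique_clones": 0,
                             "pct_expanded": np.nan,
                             "mean_clone_size": np.nan})
                continue
            n = len(cells)
            expanded = (cells["global_size"] >= EXPANDED_MIN_SIZE).sum()
            if size_scope == "global":
                per_clone = cells.groupby("clone_id")["global_size"].first()
            else:
                per_clone = cells.groupby("clone_id")["barcode"].size()
            rows.append({
                "cluster_id": k, "condition": cond,
                "n_cells_with_tcr": int(n),
                "n_unique_clones": int(cells["clone_id"].nunique()),
                "pct_expanded": 100.0 * expanded / n,
                "mean_clone_size": float(per_clone.mean()),
            })
    return pd.DataFrame(rows)


def clone_sharing(assignment: CloneAssignment, labels: dict[str, int],
                  conditions: dict[str, str]) -> dict[str, dict]:
    """Cross-cluster clone-sharing matrices, one per condition.

    Entry (i, j), i != j, is the percent of clonal (expanded) cells in
    cluster i whose clone also has at least one cell in cluster j; the
    diagonal is fixed at 100 by convention.  ``pct_shared_any`` is the percent
    of clonal cells in i whose clone appears in at least one other cluster.
    Clusters without clonal cells score 0 everywhere.
    """
    df = _clone_frame(assignment, labels, conditions)
    all_clusters = sorted(set(labels.values()))
    out = {}
    for cond in sorted(set(conditions.values())):
        sub = df[df["condition"] == cond]
        clone_clusters = sub.groupby("clone_id")["cluster"].agg(set)
        K = len(all_clusters)
        mat = np.zeros((K, K))
        shared_any = np.zeros(K)
        for a, ki in enumerate(all_clusters):
            cells = sub[(sub["cluster"] == ki)
                        & (sub["global_size"] >= EXPANDED_MIN_SIZE)]
            n_clonal = len(cells)
            mat[a, a] = 100.0
            if n_clonal == 0:
                mat[a, a] = 100.0
                continue
            present = cells["clone_id"].map(clone_clusters)
            for b, kj in enumerate(all_clusters):
                if ki == kj:
                    continue
                mat[a, b] = 100.0 * present.apply(lambda s: kj in s).sum() / n_clonal
            shared_any[a] = 100.0 * present.apply(
                lambda s: len(s - {ki}) > 0).sum() / n_clonal
        out[cond] = {
            "matrix": pd.DataFrame(mat, index=all_clusters,
                                   columns=all_clusters),
            "pct_shared_any": pd.Series(shared_any, index=all_clusters,
                                        name="pct_shared_any"),
        }
    return out


def clone_occupancy(assignment: CloneAssignment, labels: dict[str, int],
                    clone_id: int) -> pd.Series:
    """Per-cluster cell counts for one clone (sums to the clone's size)."""
    cells = [bc for bc, cl in assignment.barcode_to_clone.items()
             if cl == clone_id and bc in labels]
    occ = pd.Series([labels[bc] for bc in cells]).value_counts().sort_index()
    occ.name = f"clone_{clone_id}"
    return occ
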