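"""Regulon construction, AUCell-style activity scoring, differential activity.

A regulon is a transcription factor together with its putative target genes.
Here targets are selected by a declared co-expression heuristic — absolute
Spearman correlation with the TF across cells — rather than motif-based
pruning; externally derived regulon lists (e.g. from a full regulatory-network
pipeline) can be supplied instead and scored identically.

Activity is the AUCell statistic: for each cell, genes are ranked by
descending expression (ties broken deterministically by gene index); with
T = ceil(top_fraction * G), the raw score is the area under the gene-set
recovery curve over the top T ranks, normalized by the maximum attainable
area, giving a value in [0, 1] that is invariant under any strictly monotone
transform of the cell's expression vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .errors import ConfigError
from .stats import bh_adjust, rank_sum_test

MIN_REGULON_SIZE = 10
MIN_CELLS_PER_GROUP = 3


@dataclass
class Regulon:
    tf: str
    targets: list[str]
    weights: list[float]

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ConfigError(f"regulon {self.tf}: TF listed among targets")
        if len(set(self.targets)) != len(self.targets):
            raise ConfigError(f"regulon {self.tf}: duplicate targets")

    @property
    def genes(self) -> list[str]:
        return [self.tf] + list(self.targets)

    @property
    def size(self) -> int:
        return 1 + len(self.targets)


def build_regulons(normalized: sp.spmatrix, gene_ids, tf_list,
                   n_top_targets: int = 20, min_corr: float = 0.1,
                   min_size: int = MIN_REGULON_SIZE) -> list[Regulon]:
    """Correlation-based regulons: top targets by |Spearman rho| with the TF.

    TFs absent from the panel or with constant expression are skipped with a
    warning; regulons smaller than ``min_size`` genes (TF included) are
    dropped.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    dense = np.asarray(sp.csr_matrix(normalized).todense(), dtype=float)
    index = {g: i for i, g in enumerate(gene_ids)}
    # rank-transform once: Spearman = Pearson on midranks
    ranks = np.apply_along_axis(rankdata, 1, dense)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    regulons = []
    for tf in tf_list:
        if tf not in index:
            warnings.warn(f"TF {tf!r} not in gene panel; skipped")
            continue
        ti = index[tf]
        if norms[ti] == 0:
            warnings.warn(f"TF {tf!r} has constant expression; skipped")
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = ranks @ ranks[ti] / (norms * norms[ti])
        rho[norms == 0] = 0.0
        rho[ti] = 0.0  # exclude the TF itself
        order = np.lexsort((np.arange(len(rho)), -np.abs(rho)))
        chosen = [int(i) for i in order[:n_top_targets]
                  if abs(rho[i]) >= min_corr]
        if 1 + len(chosen) < min_size:
            warnings.warn(f"regulon {tf!r} below min size {min_size}; dropped")
            continue
        regulons.append(Regulon(tf=str(tf),
                                targets=[str(gene_ids[i]) for i in chosen],
                                weights=[float(abs(rho[i])) for i in chosen]))
    return regulons


def aucell_score(normalized: sp.spmatrix, gene_ids, regulon: Regulon,
                 top_fraction: float = 0.05) -> np.ndarray:
    """Per-cell normalized recovery-curve AUC for one regulon.

    With the cell's genes sorted by descending expression (ties broken by
    gene index), hits(k) is the number of regulon genes among the top k;
    raw = sum_{k=1..T} hits(k) and max = sum_{k=1..T} min(k, m) for a regulon
    of m genes, so AUC = raw / max lies in [0, 1].  Regulon genes missing
    from the panel are ignored; an empty intersection scores 0 with a warning.
    """
    if not 0 < top_fraction <= 1:
        raise ConfigError("top_fraction must lie in (0, 1]")
    gene_ids = np.asarray(gene_ids, dtype=object)
    index = {g: i for i, g in enumerate(gene_ids)}
    members = np.array([index[g] for g in regulon.genes if g in index])
    G = len(gene_ids)
    T = ceil(top_fraction * G)
    if members.size == 0:
        warnings.warn(f"regulon {regulon.tf!r}: no genes in panel; AUC=0")
        return np.zeros(sp.csr_matrix(normalized).shape[1])
    m = members.size
    dense = np.asarray(sp.csr_matrix(normalized).todense(), dtype=float)
    # stable argsort on -expr keeps gene-index order within ties
    order = np.argsort(-dense, axis=0, kind="stable")
    mask = np.zeros(G, dtype=bool)
    mask[members] = True
    hit_rows = mask[order[:T]]                       # T x cells
    weights = (T - np.arange(T))[:, None]            # rank r contributes T - r
    raw = (hit_rows * weights).sum(axis=0)
    max_auc = sum(min(k, m) for k in range(1, T + 1))
    return raw / max_auc


def score_regulons(normalized: sp.spmatrix, gene_ids,
                   regulons: list[Regulon],
                   top_fraction: float = 0.05) -> pd.DataFrame:
    """Regulon x cell activity matrix (rows named by TF)."""
    rows = {r.tf: aucell_score(normalized, gene_ids, r, top_fraction)
            for r in regulons}
    return pd.DataFrame(rows).T


def differential_regulon(activity: pd.DataFrame, groups,
                         min_cells: int = MIN_CELLS_PER_GROUP) -> pd.DataFrame:
    """Wilcoxon rank-sum differential activity per regulon.

    ``groups`` is a per-cell label vector.  With two levels, each regulon is
    tested first-vs-second; with more, one-vs-rest per level.  P-values are
    BH-adjusted across regulons within each comparison; effect is the
    difference of group median activities (group minus rest).
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    frames = []
    for level in levels if len(levels) > 2 else levels[:1]:
        in_g = groups == level
        rest = ~in_g
        if len(levels) == 2:
            rest = groups == levels[1]
        if in_g.sum() < min_cells or rest.sum() < min_cells:
            warnings.warn(f"group {level!r} has < {min_cells} cells; skipped")
            continue
        rows = []
        for tf, vals in activity.iterrows():
            v = vals.to_numpy(dtype=float)
            res = rank_sum_test(v[in_g], v[rest])
            rows.append({"regulon": tf, "group": level,
                         "p_value": res.p_value,
                         "effect": float(np.median(v[in_g]) - np.median(v[rest]))})
        sub = pd.DataFrame(rows)
        sub["adjusted_p"] = bh_adjust(sub["p_value"].to_numpy())
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["regulon", "group", "p_value", "effect",
                                     "adjusted_p"])
    return pd.concat(frames, ignore_index=True)


def regulons_to_frame(regulons: list[Regulon]) -> pd.DataFrame:
    """Two-column (tf, target) TSV layout with optional weight."""
    rows = []
    for r in regulons:
        for t, w in zip(r.targets, r.weights):
            rows.append({"tf": r.tf, "target": t, "weight": w})
    return pd.DataFrame(rows, columns=["tf", "target", "weight"])


def regulons_from_frame(df: pd.DataFrame) -> list[Regulon]:
    out = []
    for tf, sub in df.groupby("tf", sort=True):
        weights = (sub["weight"].astype(float).tolist()
                   if "weight" in sub.columns else [1.0] * len(sub))
        out.append(Regulon(tf=str(tf), targets=sub["target"].tolist(),
                           weights=weights))
    return out
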