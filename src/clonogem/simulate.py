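"""Synthetic paired expression + clonotype data with planted structure.

Every downstream stage of the pipeline (QC, clustering, markers, clonal
statistics, regulon scoring, topic modelling) is exercised against data from
this module, whose planted parameters are recorded in :class:`GroundTruth` so
recovery can be tested quantitatively.

The generator emulates, at desk scale, the structure of a paired
scRNA-seq/scTCR-seq experiment on tumor-infiltrating T cells from two tumor
conditions: cells drawn from cluster-specific expression programs with
per-cell library sizes and a Beta-distributed mitochondrial fraction; clone
sizes from a truncated discrete power law with controllable cross-cluster
sharing and an optional singleton-only (naive-like) cluster; planted
TF->target co-expression regulons active in designated clusters; and UMI
tokens emitted from a three-layer topic tree by nested stick-breaking.

Reproducibility: one integer seed in :class:`SimConfig`; each generator draws
from a named substream derived from it, so the order in which stages run does
not change any stage's output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .io_formats import ContigRecord, GeneCellCounts

_CONDITIONS = ("B16", "B16-IL33")


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    The defaults describe a small but realistic two-condition T-cell
    experiment: ~1000-gene panel, six phenotypic clusters, log-normal library
    sizes around 2000 UMIs, ~1% of genes mitochondrial with a heavy-tailed
    per-cell mitochondrial proportion, and a truncated power-law clone-size
    law.
    """

    n_genes: int = 1000
    n_cells: int = 2000
    n_clusters: int = 6
    conditions: Sequence[str] = _CONDITIONS
    condition_props: Sequence[float] = (0.5, 0.5)
    cluster_props: Sequence[float] | None = None  # uniform if None

    # expression programs
    n_markers_per_cluster: int = 20
    marker_fold: float = 5.0
    noise_level: float = 0.05      # background admixture weight
    disjoint_programs: bool = False

    # library sizes / mitochondria
    library_log_mean: float = float(np.log(2000.0))
    library_log_sd: float = 0.35
    min_library: int = 50
    mito_gene_fraction: float = 0.013
    mito_mean: float = 0.02
    mito_concentration: float = 12.0  # Beta concentration; low => heavy tail

    # clonotypes
    clone_power: float = 2.5
    clone_max_size: int = 50
    sharing_rate: float = 0.0
    expanded_fraction: float | Mapping[int, float] | None = None
    singleton_clusters: Sequence[int] = ()
    tra_rate: float = 0.85  # fraction of cells that also report a TRA contig

    # regulons
    n_regulons: int = 2
    targets_per_regulon: int = 20
    regulon_strength: float = 3.0  # mean added UMIs per regulon gene when active

    # topic tree
    branching: Sequence[int] = (5, 4, 3)
    alpha_stop: float = 1.0
    alpha_branch: float = 1.0
    topic_eta: float = 0.1
    disjoint_node_supports: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.n_genes < 1 or self.n_cells < 1:
            raise ConfigError("n_genes and n_cells must be positive")
        if not 0 <= self.noise_level <= 1:
            raise ConfigError("noise_level must lie in [0, 1]")
        if not 0 <= self.sharing_rate <= 1:
            raise ConfigError("sharing_rate must lie in [0, 1]")
        if not 0 <= self.mito_gene_fraction < 1:
            raise ConfigError("mito_gene_fraction must lie in [0, 1)")
        if len(self.conditions) != len(self.condition_props):
            raise ConfigError("conditions and condition_props length mismatch")
        if self.clone_max_size < 1:
            raise ConfigError("clone_max_size must be >= 1")
        if any(b < 1 for b in self.branching):
            raise ConfigError("branching factors must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def substream(self, name: str) -> np.random.Generator:
        """Named RNG substream: deterministic, independent of stage order."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % (2**31),
                                    zlib.crc32(name.encode())]))


@dataclass
class GroundTruth:
    """Planted parameters of one simulated dataset (JSON-serializable)."""

    seed: int
    n_cells_per_condition: dict = field(default_factory=dict)
    cluster_profiles: np.ndarray | None = None   # clusters x genes, rows sum to 1
    cluster_assignments: np.ndarray | None = None
    conditions: np.ndarray | None = None
    library_sizes: np.ndarray | None = None
    mito_fractions: np.ndarray | None = None
    clone_table: dict | None = None              # clone_id -> {size, occupancy}
    clone_of_cell: dict | None = None            # barcode -> clone_id
    expanded_fraction: dict | None = None
    regulon_truth: dict | None = None            # tf -> {targets, active_clusters}
    topic_truth: dict | None = None              # node dists + per-cell node counts

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            raise TypeError(type(x))
        return json.dumps(asdict(self), default=conv, sort_keys=True)


def _gene_names(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gene panel with the first ``mito_gene_fraction`` of genes named mt-*."""
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    names = [f"mt-G{i}" for i in range(n_mito)]
    names += [f"Gene{i}" for i in range(config.n_genes - n_mito)]
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[:n_mito] = True
    return np.array(names, dtype=object), mito_mask


def _cluster_profiles(config: SimConfig, rng: np.random.Generator,
                      nuclear_idx: np.ndarray) -> np.ndarray:
    """Per-cluster expression programs over the full gene panel.

    Baseline weights are log-normal; each cluster multiplies its own block of
    marker genes by ``marker_fold``.  With ``disjoint_programs`` the nuclear
    genes are partitioned across clusters instead (support containment is
    then exact at noise 0).
    """
    G = config.n_genes
    K = config.n_clusters
    profiles = np.zeros((K, G))
    if config.disjoint_programs:
        parts = np.array_split(nuclear_idx, K)
        for k in range(K):
            w = rng.lognormal(0.0, 1.0, size=len(parts[k]))
            profiles[k, parts[k]] = w / w.sum()
        return profiles
    base = rng.lognormal(0.0, 1.0, size=G)
    base[~np.isin(np.arange(G), nuclear_idx)] = 0.0
    for k in range(K):
        prof = base.copy()
        lo = k * config.n_markers_per_cluster
        hi = lo + config.n_markers_per_cluster
        markers = nuclear_idx[lo % len(nuclear_idx):][:config.n_markers_per_cluster]
        if hi <= len(nuclear_idx):
            markers = nuclear_idx[lo:hi]
        prof[markers] *= config.marker_fold
        profiles[k] = prof / prof.sum()
    return profiles


def simulate_expression(config: SimConfig) -> tuple[GeneCellCounts, GroundTruth]:
    """Draw a UMI count matrix from cluster-specific multinomial programs.

    Each cell's nuclear counts are multinomial over
    ``(1 - noise) * cluster_profile + noise * background``; the mitochondrial
    share of the library is a per-cell Beta draw spread over the mt- genes, so
    QC filtering has genuine positives to remove.
    """
    rng = config.substream("expression")
    G, N, K = config.n_genes, config.n_cells, config.n_clusters
    gene_ids, mito_mask = _gene_names(config)
    nuclear_idx = np.flatnonzero(~mito_mask)
    if len(nuclear_idx) == 0:
        raise ConfigError("no nuclear genes left after mito designation")

    cond_labels = rng.choice(len(config.conditions), size=N,
                             p=np.asarray(config.condition_props, dtype=float)
                             / np.sum(config.condition_props))
    props = (np.full(K, 1.0 / K) if config.cluster_props is None
             else np.asarray(config.cluster_props, dtype=float))
    props = props / props.sum()
    clusters = rng.choice(K, size=N, p=props)

    profiles = _cluster_profiles(config, rng, nuclear_idx)
    background = profiles.mean(axis=0)
    mixed = (1 - config.noise_level) * profiles + config.noise_level * background
    mixed /= mixed.sum(axis=1, keepdims=True)

    libs = np.maximum(config.min_library, np.round(rng.lognormal(
        config.library_log_mean, config.library_log_sd, size=N))).astype(int)
    a = config.mito_mean * config.mito_concentration
    b = (1 - config.mito_mean) * config.mito_concentration
    mito_frac = rng.beta(a, b, size=N) if mito_mask.any() else np.zeros(N)

    mito_profile = np.zeros(G)
    if mito_mask.any():
        w = rng.lognormal(0.0, 0.5, size=int(mito_mask.sum()))
        mito_profile[mito_mask] = w / w.sum()

    cols, rows, vals = [], [], []
    for i in range(N):
        n_mito = rng.binomial(libs[i], mito_frac[i])
        counts = rng.multinomial(libs[i] - n_mito, mixed[clusters[i]])
        if n_mito:
            counts = counts + rng.multinomial(n_mito, mito_profile)
        nz = np.flatnonzero(counts)
        rows.append(nz)
        cols.append(np.full(len(nz), i))
        vals.append(counts[nz])
    matrix = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(G, N), dtype=np.int64)

    barcodes = np.array([f"CELL{i:06d}-1" for i in range(N)], dtype=object)
    cond_names = np.array([config.conditions[c] for c in cond_labels],
                          dtype=object)
    meta = pd.DataFrame({"sample": cond_names, "condition": cond_names},
                        index=barcodes)
    counts_obj = GeneCellCounts(matrix, gene_ids, barcodes, meta)
    truth = GroundTruth(
        seed=config.seed,
        n_cells_per_condition={c: int((cond_names == c).sum())
                               for c in config.conditions},
        cluster_profiles=profiles,
        cluster_assignments=clusters,
        conditions=cond_names,
        library_sizes=libs,
        mito_fractions=mito_frac,
    )
    return counts_obj, truth


# ---------------------------------------------------------------------------
# clonotypes
# ---------------------------------------------------------------------------

def _power_law_sizes(rng: np.random.Generator, n: int, gamma: float,
                     smax: int, smin: int = 1) -> np.ndarray:
    sizes = np.arange(smin, smax + 1)
    p = sizes.astype(float) ** (-gamma)
    p /= p.sum()
    return rng.choice(sizes, size=n, p=p)


def _cdr3_nt(clone_index: int) -> str:
    """Deterministic unique CDR3 nucleotide string for a planted clone."""
    alphabet = "ACGT"
    body = []
    x = clone_index
    for _ in range(12):
        body.append(alphabet[x % 4])
        x //= 4
    return "TGTGC" + "".join(body) + "TTT"


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _cdr3_aa(nt: str) -> str:
    return "C" + "".join(_AA[(ord(c) * 7 + i) % 20]
                         for i, c in enumerate(nt[5:13])) + "F"


def simulate_clonotypes(
    config: SimConfig,
    cluster_assignments: np.ndarray,
    conditions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Plant a clonal structure on cells with known cluster labels.

    Within each condition, cells of clusters listed in
    ``singleton_clusters`` always receive singleton clones (a naive-like
    compartment).  For the rest, either clone sizes are drawn from the
    truncated power law until cells are exhausted, or — when
    ``expanded_fraction`` is set — each cell is independently marked
    "expanded" with the configured per-cluster probability and the marked
    cells are grouped into clones of size >= 2.  ``sharing_rate`` is the
    probability that each additional cell of a clone is recruited from a
    different cluster than the clone's home cluster.

    Returns a contig table in the Cell Ranger dialect (one productive TRB per
    cell, plus a TRA for a configurable fraction) and a GroundTruth update
    with the clone table.
    """
    rng = config.substream("clonotypes")
    clusters = np.asarray(cluster_assignments)
    N = len(clusters)
    if conditions is None:
        conditions = np.array(["pooled"] * N, dtype=object)
    conditions = np.asarray(conditions, dtype=object)
    barcodes = np.array([f"CELL{i:06d}-1" for i in range(N)], dtype=object)

    clone_of_cell = np.full(N, -1, dtype=int)
    next_clone = 0
    clone_meta: dict[int, dict] = {}

    for cond in pd.unique(conditions):
        cond_idx = np.flatnonzero(conditions == cond)
        singleton_mask = np.isin(clusters[cond_idx], config.singleton_clusters)
        free = list(cond_idx[~singleton_mask])
        rng.shuffle(free)

        if config.expanded_fraction is not None:
            expanded_cells: list[int] = []
            remaining: list[int] = []
            for i in free:
                frac = (config.expanded_fraction.get(int(clusters[i]), 0.0)
                        if isinstance(config.expanded_fraction, Mapping)
                        else float(config.expanded_fraction))
                (expanded_cells if rng.random() < frac else remaining).append(i)
            next_clone = _group_into_clones(
                config, rng, expanded_cells, clusters, clone_of_cell,
                clone_meta, next_clone, min_size=2)
            for i in remaining:
                clone_of_cell[i] = next_clone
                clone_meta[next_clone] = {"home": int(clusters[i])}
                next_clone += 1
        else:
            next_clone = _group_into_clones(
                config, rng, free, clusters, clone_of_cell, clone_meta,
                next_clone, min_size=1)

        for i in cond_idx[singleton_mask]:
            clone_of_cell[i] = next_clone
            clone_meta[next_clone] = {"home": int(clusters[i])}
            next_clone += 1

    # contig table
    v_pool = [f"TRBV{k}" for k in range(1, 21)]
    j_pool = [f"TRBJ{k}-{m}" for k in (1, 2) for m in range(1, 6)]
    clone_vj = {c: (v_pool[rng.integers(len(v_pool))],
                    j_pool[rng.integers(len(j_pool))])
                for c in clone_meta}
    rows = []
    for i in range(N):
        c = int(clone_of_cell[i])
        v, j = clone_vj[c]
        nt = _cdr3_nt(c)
        rows.append({"barcode": barcodes[i], "chain": "TRB", "v_gene": v,
                     "j_gene": j, "cdr3": _cdr3_aa(nt), "cdr3_nt": nt,
                     "productive": "True", "umis": int(rng.integers(2, 40))})
        if rng.random() < config.tra_rate:
            ant = _cdr3_nt(c + 10_000_000)
            rows.append({"barcode": barcodes[i], "chain": "TRA",
                         "v_gene": f"TRAV{1 + c % 15}", "j_gene": f"TRAJ{1 + c % 40}",
                         "cdr3": _cdr3_aa(ant), "cdr3_nt": ant,
                         "productive": "True", "umis": int(rng.integers(1, 20))})
    contig_table = pd.DataFrame(rows)

    clone_table = {}
    for c in clone_meta:
        members = np.flatnonzero(clone_of_cell == c)
        occ = pd.Series(clusters[members]).value_counts().to_dict()
        clone_table[int(c)] = {
            "size": int(len(members)),
            "occupancy": {int(k): int(v) for k, v in occ.items()},
            "condition": str(conditions[members[0]]),
        }
    truth = GroundTruth(
        seed=config.seed,
        clone_table=clone_table,
        clone_of_cell={str(barcodes[i]): int(clone_of_cell[i])
                       for i in range(N)},
        expanded_fraction=(dict(config.expanded_fraction)
                           if isinstance(config.expanded_fraction, Mapping)
                           else {"all": config.expanded_fraction}
                           if config.expanded_fraction is not None else None),
    )
    return contig_table, truth


def _group_into_clones(config, rng, pool: list[int], clusters, clone_of_cell,
                       clone_meta, next_clone: int, min_size: int) -> int:
    """Partition ``pool`` into clones with power-law sizes and sharing."""
    pool = list(pool)
    by_cluster: dict[int, list[int]] = {}
    for i in pool:
        by_cluster.setdefault(int(clusters[i]), []).append(i)
    last_clone_in: dict[int, int] = {}
    n_left = len(pool)
    while n_left > 0:
        size = int(_power_law_sizes(rng, 1, config.clone_power,
                                    config.clone_max_size, smin=min_size)[0])
        size = min(size, n_left)
        nonempty = [k for k, v in by_cluster.items() if v]
        home = nonempty[rng.integers(len(nonempty))]
        members = []
        for j in range(size):
            others = [k for k in by_cluster if by_cluster[k] and k != home]
            if j > 0 and others and rng.random() < config.sharing_rate:
                src = others[rng.integers(len(others))]
            elif by_cluster.get(home):
                src = home
            else:
                break  # home pool exhausted; close the clone early
            members.append(by_cluster[src].pop())
        if min_size > 1 and len(members) == 1:
            # an expanded-marked cell must not end up in a singleton clone:
            # attach it to an earlier clone anchored in the same cluster
            k = int(clusters[members[0]])
            if k in last_clone_in:
                clone_of_cell[members[0]] = last_clone_in[k]
                n_left -= 1
                continue
        for i in members:
            clone_of_cell[i] = next_clone
        clone_meta[next_clone] = {"home": int(home)}
        last_clone_in[home] = next_clone
        next_clone += 1
        n_left -= len(members)
    return next_clone


# ---------------------------------------------------------------------------
# regulons
# ---------------------------------------------------------------------------

def simulate_regulons(
    config: SimConfig,
    counts: GeneCellCounts,
    cluster_assignments: np.ndarray,
) -> tuple[GeneCellCounts, GroundTruth]:
    """Overlay planted TF->target co-expression programs on a count matrix.

    For each planted regulon, a TF gene and ``targets_per_regulon`` target
    genes receive extra Poisson counts in cells of the regulon's active
    cluster, with a shared per-cell Gamma activity factor that induces
    TF-target correlation.
    """
    rng = config.substream("regulons")
    clusters = np.asarray(cluster_assignments)
    G, N = counts.matrix.shape
    if config.n_regulons * (config.targets_per_regulon + 1) > G:
        raise ConfigError("not enough genes for the requested regulons")
    nuclear = np.flatnonzero(
        ~np.char.startswith(counts.gene_ids.astype(str), "mt-"))
    picks = rng.choice(nuclear, size=config.n_regulons
                       * (config.targets_per_regulon + 1), replace=False)
    dense = counts.matrix.toarray().astype(np.int64)
    regulon_truth = {}
    for r in range(config.n_regulons):
        block = picks[r * (config.targets_per_regulon + 1):
                      (r + 1) * (config.targets_per_regulon + 1)]
        tf_idx, target_idx = int(block[0]), block[1:]
        active_cluster = int(r % config.n_clusters)
        active_cells = np.flatnonzero(clusters == active_cluster)
        activity = rng.gamma(2.0, config.regulon_strength / 2.0,
                             size=len(active_cells))
        for gi in np.concatenate([[tf_idx], target_idx]):
            dense[gi, active_cells] += rng.poisson(activity)
        regulon_truth[str(counts.gene_ids[tf_idx])] = {
            "targets": [str(counts.gene_ids[t]) for t in target_idx],
            "active_clusters": [active_cluster],
        }
    new_counts = GeneCellCounts(sp.csr_matrix(dense), counts.gene_ids,
                                counts.barcodes, counts.cell_meta.copy())
    truth = GroundTruth(seed=config.seed, regulon_truth=regulon_truth)
    return new_counts, truth


# ---------------------------------------------------------------------------
# topic tree
# ---------------------------------------------------------------------------

def simulate_topic_counts(config: SimConfig) -> tuple[GeneCellCounts, GroundTruth]:
    """Emit UMI tokens from a three-layer topic tree by nested stick-breaking.

    Per cell: every internal tree node gets a stop probability
    v ~ Beta(1, alpha_stop) (leaves stop with probability 1) and a child
    distribution ~ Dirichlet(alpha_branch / b); a token walks from the root,
    stopping at a node or descending to a sampled child, then draws its gene
    from that node's distribution.  True per-cell node token counts are
    recorded, so row sums of the truth matrix equal library sizes by
    construction.
    """
    from .gems import build_tree  # local import to avoid a cycle

    rng = config.substream("topics")
    tree = build_tree(tuple(config.branching))
    n_nodes = tree.n_nodes
    G, N = config.n_genes, config.n_cells
    gene_ids = np.array([f"Gene{i}" for i in range(G)], dtype=object)

    # node gene distributions
    node_dists = np.zeros((n_nodes, G))
    if config.disjoint_node_supports:
        parts = np.array_split(np.arange(G), n_nodes)
        for n in range(n_nodes):
            w = rng.lognormal(0.0, 0.5, size=len(parts[n]))
            node_dists[n, parts[n]] = w / w.sum()
    else:
        node_dists = rng.dirichlet(np.full(G, max(config.topic_eta, 1e-3)),
                                   size=n_nodes)

    libs = np.maximum(config.min_library, np.round(rng.lognormal(
        config.library_log_mean, config.library_log_sd, size=N))).astype(int)

    cell_node_counts = np.zeros((N, n_nodes), dtype=np.int64)
    mat = np.zeros((G, N), dtype=np.int64)
    internal = [n for n in range(n_nodes) if tree.children[n]]
    for i in range(N):
        v = np.ones(n_nodes)
        v[internal] = rng.beta(1.0, config.alpha_stop, size=len(internal))
        child_p = {}
        roots = tree.depth1_nodes
        child_p[-1] = rng.dirichlet(
            np.full(len(roots), config.alpha_branch / len(roots)))
        for n in internal:
            b = len(tree.children[n])
            child_p[n] = rng.dirichlet(np.full(b, config.alpha_branch / b))
        # per-cell node weights by walking the tree
        weights = np.zeros(n_nodes)
        reach = {}
        for r, pr in zip(roots, child_p[-1]):
            reach[r] = pr
        order = sorted(range(n_nodes), key=lambda n: tree.depth[n])
        for n in order:
            if n not in reach:
                continue
            weights[n] = reach[n] * v[n]
            if tree.children[n]:
                pass_mass = reach[n] * (1 - v[n])
                for c, pc in zip(tree.children[n], child_p[n]):
                    reach[c] = pass_mass * pc
        weights /= weights.sum()
        node_counts = rng.multinomial(libs[i], weights)
        cell_node_counts[i] = node_counts
        for n in np.flatnonzero(node_counts):
            mat[:, i] += rng.multinomial(node_counts[n], node_dists[n])

    barcodes = np.array([f"CELL{i:06d}-1" for i in range(N)], dtype=object)
    meta = pd.DataFrame({"sample": ["sim"] * N, "condition": ["sim"] * N},
                        index=barcodes)
    counts_obj = GeneCellCounts(sp.csr_matrix(mat), gene_ids, barcodes, meta)
    truth = GroundTruth(
        seed=config.seed,
        library_sizes=libs,
        topic_truth={
            "branching": list(config.branching),
            "node_distributions": node_dists.tolist(),
            "cell_node_counts": cell_node_counts.tolist(),
        },
    )
    return counts_obj, truth
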