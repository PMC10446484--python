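"""Gene expression modules (GEMs) from a tree-structured topic model.

The model is a truncated nested-HDP topic model over UMI tokens: a fixed
three-layer tree (default branching factors 5, 4, 3 below a virtual root,
85 nodes in total) where every node is a GEM, i.e. a distribution over genes.
Each cell owns nested stick-breaking weights over root-to-leaf paths: at
every internal node the cell either stops (emitting from that node's gene
distribution) or descends to a child.  GEMs near the root are therefore
shared across broad cell populations while leaf GEMs capture specialized
programs.

Inference is collapsed Gibbs sampling over token-to-node assignments with the
per-cell stick-breaking weights (Beta(1, alpha_stop) stop sticks,
Dirichlet(alpha_branch / b) child choices) and the Dirichlet(eta) gene
emissions integrated out.  The token unit is the UMI: a count of c for gene g
contributes c tokens, so the cell-by-GEM count matrix rows always sum to the
cell's library size (token conservation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln

from .errors import ConfigError, NumericalError
from .io_formats import GeneCellCounts
from .stats import bh_adjust, rank_sum_test

DEFAULT_BRANCHING = (5, 4, 3)


@dataclass(frozen=True)
class TopicTree:
    """Fixed topic tree below a virtual root.

    Nodes are numbered breadth-first: all depth-1 nodes, then depth-2, then
    depth-3, so a parent's index always precedes its children's.
    """

    branching: tuple[int, ...]
    parent: np.ndarray       # -1 for depth-1 nodes
    depth: np.ndarray        # 1-based
    children: tuple[tuple[int, ...], ...]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def depth1_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.parent == -1)

    def nodes_at_depth(self, d: int) -> np.ndarray:
        return np.flatnonzero(self.depth == d)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": np.arange(self.n_nodes),
                             "parent": self.parent, "depth": self.depth})


def build_tree(branching: tuple[int, ...] = DEFAULT_BRANCHING) -> TopicTree:
    """Build the topic tree for the given branching factors.

    The node count is b1 + b1*b2 + ... (the virtual root is not a GEM and is
    not counted); the default (5, 4, 3) yields 85 nodes.
    """
    branching = tuple(int(b) for b in branching)
    if not branching or any(b < 1 for b in branching):
        raise ConfigError("branching factors must all be >= 1")
    parent: list[int] = []
    depth: list[int] = []
    prev_level = [-1]  # virtual root
    for d, b in enumerate(branching, start=1):
        level = []
        for u in prev_level:
            for _ in range(b):
                level.append(len(parent))
                parent.append(u)
                depth.append(d)
        prev_level = level
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    for c, u in enumerate(parent):
        if u >= 0:
            children[u].append(c)
    return TopicTree(branching=branching,
                     parent=np.asarray(parent, dtype=np.int64),
                     depth=np.asarray(depth, dtype=np.int64),
                     children=tuple(tuple(c) for c in children))


@dataclass(frozen=True)
class NhdpPriors:
    """Hyperparameters of the collapsed sampler.

    eta is the symmetric Dirichlet concentration on each node's gene
    distribution; alpha_stop the Beta(1, alpha_stop) stop-stick prior;
    alpha_branch the total Dirichlet mass over a node's children.
    """

    eta: float = 0.1
    alpha_stop: float = 1.0
    alpha_branch: float = 1.0

    def __post_init__(self) -> None:
        if min(self.eta, self.alpha_stop, self.alpha_branch) <= 0:
            raise ConfigError("priors must be positive")


@dataclass
class NodeGeneDistribution:
    """Posterior gene distributions per node (Dirichlet-smoothed counts)."""

    counts: np.ndarray        # nodes x genes token counts
    eta: float
    gene_ids: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        sm = self.counts + self.eta
        return sm / sm.sum(axis=1, keepdims=True)


@dataclass
class CellGemCounts:
    """Cell x GEM token counts plus the stick-breaking hyperparameters."""

    counts: np.ndarray        # cells x nodes, integer
    barcodes: np.ndarray
    alpha_stop: float
    alpha_branch: float
    mean_counts: np.ndarray | None = None  # post-burn-in average, if requested


def _tokenize(matrix: sp.spmatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand a genes x cells count matrix into per-UMI token arrays."""
    csc = sp.csc_matrix(matrix)
    cells = []
    genes = []
    for c in range(csc.shape[1]):
        sl = slice(csc.indptr[c], csc.indptr[c + 1])
        reps = csc.data[sl].astype(np.int64)
        genes.append(np.repeat(csc.indices[sl].astype(np.int64), reps))
        cells.append(np.full(int(reps.sum()), c, dtype=np.int64))
    token_cell = np.concatenate(cells) if cells else np.empty(0, np.int64)
    token_gene = np.concatenate(genes) if genes else np.empty(0, np.int64)
    lib = np.asarray(matrix.sum(axis=0)).ravel().astype(np.int64)
    return token_cell, token_gene, lib


def _make_sweep():
    from numba import njit

    @njit(cache=True)
    def sweep(token_cell, token_gene, token_node, m, M, ng, ntot, lib,
              parent, child_count, n_roots, eta, a_stop, a_branch, n_genes,
              seed):
        np.random.seed(seed)
        n_nodes = parent.shape[0]
        reach = np.empty(n_nodes)
        prob = np.empty(n_nodes)
        geta = n_genes * eta
        for t in range(token_cell.shape[0]):
            d = token_cell[t]
            g = token_gene[t]
            old = token_node[t]
            m[d, old] -= 1
            node = old
            while node != -1:
                M[d, node] -= 1
                node = parent[node]
            ng[old, g] -= 1
            ntot[old] -= 1

            total_d = lib[d] - 1
            cum = 0.0
            for n in range(n_nodes):
                u = parent[n]
                if u == -1:
                    reach[n] = (M[d, n] + a_branch / n_roots) / (total_d + a_branch)
                else:
                    desc_u = (M[d, u] - m[d, u] + a_stop) / (M[d, u] + 1.0 + a_stop)
                    below_u = M[d, u] - m[d, u]
                    choice = (M[d, n] + a_branch / child_count[u]) / (below_u + a_branch)
                    reach[n] = reach[u] * desc_u * choice
                if child_count[n] > 0:
                    stop = (m[d, n] + 1.0) / (M[d, n] + 1.0 + a_stop)
                else:
                    stop = 1.0
                p = reach[n] * stop * (eta + ng[n, g]) / (geta + ntot[n])
                prob[n] = p
                cum += p

            r = np.random.random() * cum
            new = n_nodes - 1
            acc = 0.0
            for n in range(n_nodes):
                acc += prob[n]
                if r < acc:
                    new = n
                    break

            token_node[t] = new
            m[d, new] += 1
            node = new
            while node != -1:
                M[d, node] += 1
                node = parent[node]
            ng[new, g] += 1
            ntot[new] += 1

    return sweep


_SWEEP = None


def _get_sweep():
    global _SWEEP
    if _SWEEP is None:
        _SWEEP = _make_sweep()
    return _SWEEP


def _log_joint(m, M, ng, ntot, tree: TopicTree, priors: NhdpPriors,
               n_genes: int) -> float:
    """Collapsed joint log-probability of the current token assignment.

    Sum of Dirichlet-multinomial marginals for gene emissions per node, plus
    per-cell Beta marginals of the stop sticks and Dirichlet marginals of the
    child choices (root included).
    """
    eta, a_stop, a_branch = priors.eta, priors.alpha_stop, priors.alpha_branch
    lp = 0.0
    # gene side
    lp += float(np.sum(gammaln(n_genes * eta) - gammaln(n_genes * eta + ntot)))
    nz = ng[ng > 0]
    lp += float(np.sum(gammaln(eta + nz) - gammaln(eta)))
    # stop sticks: internal nodes only; v ~ Beta(1, a_stop)
    internal = np.array([n for n in range(tree.n_nodes) if tree.children[n]])
    if internal.size:
        mm = m[:, internal].astype(float)
        MM = M[:, internal].astype(float)
        passed = MM - mm
        lp += float(np.sum(gammaln(1.0 + a_stop) - gammaln(a_stop)
                           + gammaln(mm + 1.0) + gammaln(passed + a_stop)
                           - gammaln(MM + 1.0 + a_stop)))
    # child choices, root included
    groups = [np.asarray(tree.depth1_nodes)]
    groups += [np.asarray(tree.children[n]) for n in range(tree.n_nodes)
               if tree.children[n]]
    for ch in groups:
        b = len(ch)
        Mc = M[:, ch].astype(float)
        below = Mc.sum(axis=1)
        lp += float(np.sum(gammaln(a_branch) - gammaln(below + a_branch)))
        lp += float(np.sum(gammaln(Mc + a_branch / b) - gammaln(a_branch / b)))
    return lp


def fit_nhdp(counts: GeneCellCounts, tree: TopicTree | None = None,
             priors: NhdpPriors = NhdpPriors(), n_iter: int = 200,
             burn_in: int = 100, seed: int = 0, average: bool = False,
             ) -> tuple[NodeGeneDistribution, CellGemCounts, pd.DataFrame]:
    """Fit the tree topic model by collapsed Gibbs sampling.

    Parameters
    ----------
    counts
        Post-QC UMI counts; every UMI becomes one token.
    tree
        Topic tree; defaults to branching (5, 4, 3).
    n_iter, burn_in
        Total Gibbs sweeps and how many to discard; ``n_iter > burn_in``.
    average
        When True, also return the post-burn-in average of the cell-by-GEM
        counts (real-valued) in ``CellGemCounts.mean_counts``; the integer
        ``counts`` field is always the final sample, preserving token
        conservation exactly.

    Returns
    -------
    (node gene distributions, cell-by-GEM counts, diagnostics) where
    diagnostics holds the per-iteration collapsed joint log-probability.
    """
    if tree is None:
        tree = build_tree()
    if counts.matrix.nnz == 0:
        raise ConfigError("empty count matrix")
    if n_iter <= burn_in:
        raise ConfigError("n_iter must exceed burn_in")

    token_cell, token_gene, lib = _tokenize(counts.matrix)
    n_cells = counts.n_cells
    n_genes = counts.n_genes
    n_nodes = tree.n_nodes

    rng = np.random.default_rng(seed)
    token_node = rng.integers(0, n_nodes, size=token_cell.shape[0]).astype(np.int64)

    m = np.zeros((n_cells, n_nodes), dtype=np.int64)
    M = np.zeros((n_cells, n_nodes), dtype=np.int64)
    ng = np.zeros((n_nodes, n_genes), dtype=np.int64)
    np.add.at(m, (token_cell, token_node), 1)
    np.add.at(ng, (token_node, token_gene), 1)
    # subtree counts: add each node's own count to all its ancestors
    M[:] = m
    for n in range(n_nodes - 1, -1, -1):
        u = tree.parent[n]
        if u >= 0:
            M[:, u] += M[:, n]
    ntot = ng.sum(axis=1)

    sweep = _get_sweep()
    n_roots = int(len(tree.depth1_nodes))
    parent = tree.parent.astype(np.int64)
    child_count = np.array([len(c) for c in tree.children], dtype=np.int64)

    logs = []
    mean_acc = np.zeros_like(m, dtype=float) if average else None
    n_avg = 0
    for it in range(n_iter):
        sweep(token_cell, token_gene, token_node, m, M, ng, ntot, lib,
              parent, child_count, n_roots, float(priors.eta),
              float(priors.alpha_stop), float(priors.alpha_branch), n_genes,
              int((seed + 1_000_003 * (it + 1)) % (2**31 - 1)))
        lp = _log_joint(m, M, ng, ntot, tree, priors, n_genes)
        if not np.isfinite(lp):
            raise NumericalError(f"log-probability not finite at iteration {it}")
        logs.append(lp)
        if average and it >= burn_in:
            mean_acc += m
            n_avg += 1

    diagnostics = pd.DataFrame({"iteration": np.arange(n_iter),
                                "log_joint": logs})
    node_dist = NodeGeneDistribution(counts=ng.astype(np.int64),
                                     eta=priors.eta,
                                     gene_ids=counts.gene_ids)
    cell_gem = CellGemCounts(
        counts=m.copy(), barcodes=counts.barcodes,
        alpha_stop=priors.alpha_stop, alpha_branch=priors.alpha_branch,
        mean_counts=(mean_acc / max(n_avg, 1)) if average else None)
    return node_dist, cell_gem, diagnostics


def ranked_genes(node_dist: NodeGeneDistribution, node_id: int,
                 top_n: int = 30) -> list[str]:
    """Genes most commonly assigned to one GEM, by descending token count.

    Ties break to the lower gene index.  A node with zero tokens returns an
    empty list with a warning (a prior-only ranking would be meaningless).
    """
    counts = node_dist.counts[node_id]
    if counts.sum() == 0:
        warnings.warn(f"node {node_id} has zero tokens; empty ranking")
        return []
    order = np.lexsort((np.arange(len(counts)), -counts))
    order = order[counts[order] > 0][:top_n]
    return [str(node_dist.gene_ids[i]) for i in order]


@dataclass(frozen=True)
class GemDifferentialConfig:
    alpha: float = 0.05
    min_cells: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


def gem_differential(cell_gem: CellGemCounts, groups,
                     cfg: GemDifferentialConfig = GemDifferentialConfig(),
                     ) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum test per GEM.

    Per-cell GEM counts are normalized by the cell's library size (row sum)
    before testing; a GEM is flagged significant when p < cfg.alpha.  With
    more than two group levels, each level is tested one-vs-rest.
    """
    groups = np.asarray(groups)
    counts = cell_gem.counts.astype(float)
    lib = counts.sum(axis=1, keepdims=True)
    frac = counts / np.maximum(lib, 1.0)
    levels = pd.unique(groups)
    frames = []
    for level in (levels if len(levels) > 2 else levels[:1]):
        in_g = groups == level
        rest = (groups == levels[1]) if len(levels) == 2 else ~in_g
        if in_g.sum() < cfg.min_cells or rest.sum() < cfg.min_cells:
            warnings.warn(f"group {level!r} has < {cfg.min_cells} cells; skipped")
            continue
        rows = []
        for gem in range(frac.shape[1]):
            res = rank_sum_test(frac[in_g, gem], frac[rest, gem])
            rows.append({"gem": gem, "group": level, "p_value": res.p_value})
        sub = pd.DataFrame(rows)
        sub["adjusted_p"] = bh_adjust(sub["p_value"].to_numpy())
        sub["significant"] = sub["p_value"] < cfg.alpha
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["gem", "group", "p_value", "adjusted_p",
                                     "significant"])
    return pd.concat(frames, ignore_index=True)
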