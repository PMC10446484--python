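"""Topic tree construction, Gibbs inference, ranked genes, differential GEMs."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from clonogem import CellGemCounts, GemDifferentialConfig, NhdpPriors, \
    SimConfig, build_tree, fit_nhdp, gem_differential, ranked_genes, \
    simulate_topic_counts
from clonogem.errors import ConfigError, NumericalError
from clonogem.gems import NodeGeneDistribution, _tokenize

from conftest import make_counts


@pytest.mark.parametrize("branching,expected", [
    ((5, 4, 3), 85),   # 5 + 20 + 60
    ((1, 1, 1), 3),
    ((2, 2, 2), 14),   # 2 + 4 + 8
])
def test_tree_cardinality(branching, expected):
    tree = build_tree(branching)
    assert tree.n_nodes == expected


def test_tree_structure_invariants():
    tree = build_tree((5, 4, 3))
    # breadth-first: parents precede children; leaves all at depth 3
    for n in range(tree.n_nodes):
        assert tree.parent[n] < n
        if not tree.children[n]:
            assert tree.depth[n] == 3
    assert len(tree.depth1_nodes) == 5
    assert (tree.depth[tree.nodes_at_depth(2)] == 2).all()
    assert len(tree.nodes_at_depth(3)) == 60


def test_tree_rejects_bad_branching():
    with pytest.raises(ConfigError):
        build_tree((5, 0, 3))
    with pytest.raises(ConfigError):
        build_tree(())


def test_priors_validate():
    with pytest.raises(ConfigError):
        NhdpPriors(eta=0.0)


@pytest.fixture(scope="module")
def topic_fit():
    cfg = SimConfig(n_genes=140, n_cells=150, branching=(2, 2, 2),
                    disjoint_node_supports=True,
                    library_log_mean=np.log(120), library_log_sd=0.3, seed=3)
    counts, truth = simulate_topic_counts(cfg)
    tree = build_tree((2, 2, 2))
    node_dist, cell_gem, diag = fit_nhdp(counts, tree, NhdpPriors(),
                                         n_iter=80, burn_in=50, seed=5)
    return counts, truth, tree, node_dist, cell_gem, diag


def test_token_conservation(topic_fit):
    counts, truth, tree, node_dist, cell_gem, diag = topic_fit
    lib = np.asarray(counts.matrix.sum(axis=0)).ravel()
    assert (cell_gem.counts.sum(axis=1) == lib).all()
    # gene-side bookkeeping matches the matrix total
    assert node_dist.counts.sum() == lib.sum()


def test_conservation_at_every_sweep():
    """Row sums of the cell-by-GEM counts never change across sweeps."""
    from clonogem.gems import _get_sweep

    cfg = SimConfig(n_genes=50, n_cells=30, branching=(2, 2),
                    library_log_mean=np.log(40), seed=1)
    counts, _ = simulate_topic_counts(cfg)
    tree = build_tree((2, 2))
    token_cell, token_gene, lib = _tokenize(counts.matrix)
    rng = np.random.default_rng(0)
    token_node = rng.integers(0, tree.n_nodes, token_cell.shape[0]).astype(np.int64)
    m = np.zeros((30, tree.n_nodes), dtype=np.int64)
    M = np.zeros_like(m)
    ng = np.zeros((tree.n_nodes, 50), dtype=np.int64)
    np.add.at(m, (token_cell, token_node), 1)
    np.add.at(ng, (token_node, token_gene), 1)
    M[:] = m
    for n in range(tree.n_nodes - 1, -1, -1):
        if tree.parent[n] >= 0:
            M[:, tree.parent[n]] += M[:, n]
    ntot = ng.sum(axis=1)
    sweep = _get_sweep()
    child_count = np.array([len(c) for c in tree.children], dtype=np.int64)
    for it in range(5):
        sweep(token_cell, token_gene, token_node, m, M, ng, ntot, lib,
              tree.parent, child_count, len(tree.depth1_nodes),
              0.1, 1.0, 1.0, 50, it + 1)
        assert (m.sum(axis=1) == lib).all()
        assert (ng.sum(axis=1) == ntot).all()
        assert (m >= 0).all() and (M >= 0).all() and (ng >= 0).all()


def test_seed_determinism():
    cfg = SimConfig(n_genes=60, n_cells=40, branching=(2, 2),
                    library_log_mean=np.log(50), seed=2)
    counts, _ = simulate_topic_counts(cfg)
    tree = build_tree((2, 2))
    a = fit_nhdp(counts, tree, n_iter=10, burn_in=5, seed=9)
    b = fit_nhdp(counts, tree, n_iter=10, burn_in=5, seed=9)
    assert (a[1].counts == b[1].counts).all()
    assert (a[0].counts == b[0].counts).all()
    pd.testing.assert_frame_equal(a[2], b[2])


def test_log_joint_finite_and_improving(topic_fit):
    *_, diag = topic_fit
    lp = diag["log_joint"].to_numpy()
    assert np.isfinite(lp).all()
    # strong upward trend over burn-in on identifiable data
    assert lp[-1] > lp[0]
    assert np.mean(lp[-10:]) > np.mean(lp[:10])


def test_depth1_distributions_recovered(topic_fit):
    """After optimal one-to-one node matching, the true depth-1 gene
    distributions are recovered with high cosine similarity."""
    counts, truth, tree, node_dist, cell_gem, diag = topic_fit
    true_d = np.array(truth.topic_truth["node_distributions"])
    rec = node_dist.probabilities
    tn = true_d / np.linalg.norm(true_d, axis=1, keepdims=True)
    rn = rec / np.linalg.norm(rec, axis=1, keepdims=True)
    C = tn @ rn.T
    r, c = linear_sum_assignment(-C)
    d1 = np.isin(r, tree.depth1_nodes)
    assert C[r, c][d1].mean() >= 0.8


def test_single_subtree_limit():
    """As the branch concentration approaches zero, each cell's tokens
    collapse into a single depth-1 subtree."""
    rng = np.random.default_rng(4)
    G, N = 60, 40
    dist = rng.dirichlet(np.full(20, 0.5))
    mat = np.zeros((G, N), dtype=int)
    for i in range(N):
        mat[:20, i] = rng.multinomial(100, dist)
    counts = make_counts(mat)
    tree = build_tree((2, 2))
    _, cell_gem, _ = fit_nhdp(counts, tree, NhdpPriors(alpha_branch=0.01),
                              n_iter=200, burn_in=150, seed=0)
    # assign each node to its depth-1 subtree root
    root_of = np.empty(tree.n_nodes, dtype=int)
    for n in range(tree.n_nodes):
        r = n
        while tree.parent[r] >= 0:
            r = tree.parent[r]
        root_of[n] = r
    per_root = np.zeros((len(counts.barcodes), 2))
    for n in range(tree.n_nodes):
        per_root[:, root_of[n]] += cell_gem.counts[:, n]
    frac_major = per_root.max(axis=1) / per_root.sum(axis=1)
    assert frac_major.mean() >= 0.99


def test_empty_matrix_rejected():
    counts = make_counts(np.zeros((4, 3), dtype=int))
    with pytest.raises(ConfigError):
        fit_nhdp(counts, build_tree((1, 1)), n_iter=2, burn_in=1, seed=0)


def test_iteration_budget_validated(topic_fit):
    counts, *_ = topic_fit
    with pytest.raises(ConfigError):
        fit_nhdp(counts, build_tree((2, 2)), n_iter=5, burn_in=5, seed=0)


def test_averaged_counts_option():
    cfg = SimConfig(n_genes=50, n_cells=25, branching=(2, 2),
                    library_log_mean=np.log(40), seed=6)
    counts, _ = simulate_topic_counts(cfg)
    _, cell_gem, _ = fit_nhdp(counts, build_tree((2, 2)), n_iter=12,
                              burn_in=6, seed=1, average=True)
    lib = np.asarray(counts.matrix.sum(axis=0)).ravel()
    assert np.allclose(cell_gem.mean_counts.sum(axis=1), lib)


# ---------------------------------------------------------------------------
# ranked genes
# ---------------------------------------------------------------------------

def _node_dist(counts):
    return NodeGeneDistribution(counts=np.asarray(counts), eta=0.1,
                                gene_ids=np.array(
                                    [f"g{i}" for i in range(np.asarray(counts).shape[1])],
                                    dtype=object))


def test_ranked_genes_order_and_ties():
    nd = _node_dist([[3, 10, 0], [5, 5, 0]])
    assert ranked_genes(nd, 0) == ["g1", "g0"]
    assert ranked_genes(nd, 1) == ["g0", "g1"]  # tie -> lower index first


def test_ranked_genes_empty_node_warns():
    nd = _node_dist([[0, 0, 0]])
    with pytest.warns(UserWarning, match="zero tokens"):
        assert ranked_genes(nd, 0) == []


def test_planted_signature_in_top_ranked(topic_fit):
    counts, truth, tree, node_dist, cell_gem, diag = topic_fit
    true_d = np.array(truth.topic_truth["node_distributions"])
    rec = node_dist.probabilities
    tn = true_d / np.linalg.norm(true_d, axis=1, keepdims=True)
    rn = rec / np.linalg.norm(rec, axis=1, keepdims=True)
    r, c = linear_sum_assignment(-(tn @ rn.T))
    # for a well-recovered node, its true support genes dominate the ranking
    pair = max(zip(r, c), key=lambda p: (tn @ rn.T)[p[0], p[1]])
    true_support = set(np.flatnonzero(true_d[pair[0]] > 0))
    top = ranked_genes(node_dist, pair[1], top_n=2 * len(true_support))
    top_idx = {int(g[4:]) if g.startswith("Gene") else -1 for g in top}
    assert len(true_support & top_idx) / len(true_support) >= 0.9


# ---------------------------------------------------------------------------
# differential GEMs
# ---------------------------------------------------------------------------

def _cell_gem(counts):
    counts = np.asarray(counts)
    return CellGemCounts(counts=counts,
                         barcodes=np.array([f"b{i}" for i in range(len(counts))]),
                         alpha_stop=1.0, alpha_branch=1.0)


def test_gem_differential_identical_groups():
    rng = np.random.default_rng(0)
    base = rng.multinomial(50, [0.3, 0.3, 0.4], size=20)
    cg = _cell_gem(np.vstack([base, base]))
    groups = np.array(["a"] * 20 + ["b"] * 20)
    table = gem_differential(cg, groups)
    assert not table["significant"].any()


def test_gem_differential_exact_route():
    # one GEM with values 1..6 against equal library sizes: exact p = 0.1
    counts = np.zeros((6, 2), dtype=int)
    counts[:, 0] = [1, 2, 3, 4, 5, 6]
    counts[:, 1] = [9, 8, 7, 6, 5, 4]  # library size 10 per cell
    table = gem_differential(_cell_gem(counts),
                             np.array(["a"] * 3 + ["b"] * 3))
    assert table.loc[table["gem"] == 0, "p_value"].iloc[0] == pytest.approx(0.1)


def test_gem_differential_planted_power():
    """A GEM with doubled weight in condition B is detected in >= 90% of
    seeds at n=300 cells per group."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        wa = np.array([0.25, 0.25, 0.25, 0.25])
        wb = np.array([0.40, 0.20, 0.20, 0.20])  # GEM 0 enriched ~2x
        lib = rng.integers(80, 120, size=600)
        counts = np.vstack([
            [rng.multinomial(lib[i], wa) for i in range(300)],
            [rng.multinomial(lib[300 + i], wb) for i in range(300)]])
        groups = np.array(["A"] * 300 + ["B"] * 300)
        table = gem_differential(_cell_gem(counts), groups,
                                 GemDifferentialConfig(alpha=0.05))
        if bool(table.loc[table["gem"] == 0, "significant"].iloc[0]):
            hits += 1
    assert hits >= 0.9 * n_seeds


def test_gem_differential_small_group_skipped():
    cg = _cell_gem(np.ones((5, 2), dtype=int))
    with pytest.warns(UserWarning, match="skipped"):
        table = gem_differential(cg, np.array(["a"] * 4 + ["b"]))
    assert table.empty
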