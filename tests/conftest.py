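"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from clonogem import GeneCellCounts, SimConfig, simulate_expression


@pytest.fixture(scope="session")
def small_sim():
    """300-cell, 3-cluster dataset with planted markers (session-cached)."""
    cfg = SimConfig(n_genes=200, n_cells=300, n_clusters=3,
                    n_markers_per_cluster=15, marker_fold=5.0, seed=11)
    counts, truth = simulate_expression(cfg)
    return cfg, counts, truth


def make_counts(matrix, gene_ids=None, conditions=None):
    """Wrap a dense array as GeneCellCounts with generic labels."""
    matrix = np.asarray(matrix)
    G, N = matrix.shape
    gene_ids = (np.array([f"g{i}" for i in range(G)], dtype=object)
                if gene_ids is None else np.asarray(gene_ids, dtype=object))
    barcodes = np.array([f"BC{i:04d}" for i in range(N)], dtype=object)
    conditions = (["cond"] * N if conditions is None else list(conditions))
    meta = pd.DataFrame({"sample": conditions, "condition": conditions},
                        index=barcodes)
    return GeneCellCounts(sp.csr_matrix(matrix), gene_ids, barcodes, meta)


@pytest.fixture
def qc_core_fixture():
    """6-gene x 5-cell matrix: 2 genes below the 4-cell rule, 1 cell over
    the 5% mito ceiling; filtering leaves a (4, 4) submatrix."""
    mat = np.array([
        [1, 1, 1, 1, 1],    # mt-g: in 5 cells; drives c4's mito fraction
        [10, 10, 10, 10, 3],
        [10, 10, 10, 10, 3],
        [5, 6, 7, 8, 2],
        [3, 0, 0, 0, 1],    # detected in 2 cells -> dropped
        [0, 2, 0, 0, 0],    # detected in 1 cell -> dropped
    ])
    genes = ["mt-g", "g1", "g2", "g3", "g4", "g5"]
    return make_counts(mat, gene_ids=genes)
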