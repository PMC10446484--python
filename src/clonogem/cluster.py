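"""Dimensionality reduction, SNN graph clustering, and cluster summaries.

PCA is computed on the scaled highly-variable-gene matrix; clustering builds
a shared-nearest-neighbor (SNN) graph on the PC scores — edge weights are the
Jaccard overlap of k-nearest-neighbor sets — and runs seeded Leiden modularity
optimization at a configurable resolution.  Also provides the per-cluster
composition table, hierarchical grouping of cluster mean profiles, and
per-condition kernel density grids over a 2-D embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering parameters.

    ``n_hvg`` / ``n_pcs`` default to the standard 2000 features / 50 PCs;
    ``resolution`` defaults to 1.0 (middle of the commonly used 0.8-1.4
    range).  ``snn_prune`` drops SNN edges whose Jaccard weight falls below
    the cutoff (1/15, the usual default).
    """

    n_hvg: int = 2000
    n_pcs: int = 50
    snn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigError("resolution must be positive")
        if self.n_pcs > self.n_hvg:
            raise ConfigError("n_pcs must not exceed n_hvg")
        if self.snn_k < 2:
            raise ConfigError("snn_k must be >= 2")


def run_pca(scaled: np.ndarray, n_pcs: int = 50,
            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the cells on a genes x cells scaled matrix.

    Returns (scores, explained_variance): ``scores`` is cells x n_pcs
    (projections onto the top right-singular directions of the cell x gene
    matrix), ``explained_variance`` is non-increasing.  ``n_pcs`` is capped at
    min(n_cells - 1, n_genes) with a warning.  Component signs are fixed so
    the loading of largest magnitude is positive, making runs reproducible.
    """
    X = np.asarray(scaled, dtype=float).T  # cells x genes
    max_pcs = min(X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds usable rank {max_pcs}; capped")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.sign(pca.components_[
        np.arange(n_pcs), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip, pca.explained_variance_

def snn_graph(scores: np.ndarray, k: int = 20,
              prune: float = 1.0 / 15.0) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets.

    Neighbor sets include the cell itself (so two mutual neighbors with
    identical neighborhoods get weight 1).  Edges below ``prune`` are dropped.
    """
    n = scores.shape[0]
    if n < k:
        raise ConfigError(f"need at least k={k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k).fit(scores)
    knn = nn.kneighbors_graph(scores, mode="connectivity")
    knn = knn.maximum(sp.eye(n, format="csr"))  # ensure self-membership
    shared = (knn @ knn.T).tocoo()  # |A ∩ B| for each pair with overlap
    sizes = np.asarray(knn.sum(axis=1)).ravel()
    inter = shared.data
    union = sizes[shared.row] + sizes[shared.col] - inter
    jac = inter / union
    keep = (jac >= prune) & (shared.row != shared.col)
    return sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])),
                         shape=(n, n))


def snn_cluster(scores: np.ndarray,
                cfg: ClusterConfig = ClusterConfig()) -> np.ndarray:
    """Leiden modularity clustering of the SNN graph.

    Returns 0-based labels relabeled by decreasing cluster size (cluster 0 is
    the largest).  Deterministic given ``cfg.seed``.
    """
    import igraph as ig
    import leidenalg

    graph = snn_graph(scores, k=cfg.snn_k, prune=cfg.snn_prune)
    coo = sp.triu(graph.maximum(graph.T), k=1).tocoo()
    g = ig.Graph(n=scores.shape[0],
                 edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(), resolution_parameter=cfg.resolution,
        seed=int(cfg.seed), n_iterations=2)
    raw = np.asarray(part.membership)
    return relabel_by_size(raw)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map labels to a contiguous 0-based set ordered by decreasing size."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[x] for x in labels], dtype=int)


def embed_2d(scores: np.ndarray, method: str = "umap", seed: int = 0,
             **kwargs) -> np.ndarray:
    """Pluggable 2-D embedding of PC scores.

    ``method="umap"`` uses UMAP with a fixed random state; ``method="pca"``
    simply returns the first two PCs (fast, deterministic, adequate for
    density summaries).  Only the interface (cells x 2, deterministic under a
    fixed seed) is contractual; the algorithm is swappable.
    """
    if method == "pca":
        return np.asarray(scores)[:, :2].copy()
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=int(seed), **kwargs)
        return np.asarray(reducer.fit_transform(scores), dtype=float)
    raise ConfigError(f"unknown embedding method {method!r}")


def composition(labels, conditions) -> pd.DataFrame:
    """Cluster x condition cell counts and within-condition percentages."""
    df = pd.DataFrame({"cluster_id": np.asarray(labels),
                       "condition": np.asarray(conditions)})
    rows = []
    for cond, sub in df.groupby("condition", sort=True):
        n_cond = len(sub)
        counts = sub["cluster_id"].value_counts().sort_index()
        for cl, n in counts.items():
            rows.append({"cluster_id": cl, "condition": cond,
                         "n_cells": int(n),
                         "percent": 100.0 * n / n_cond})
    return pd.DataFrame(rows)


def cluster_mean_profiles(normalized: sp.spmatrix,
                          labels: np.ndarray) -> np.ndarray:
    """Per-cluster mean of the log-normalized matrix (clusters x genes)."""
    labels = np.asarray(labels)
    mat = sp.csr_matrix(normalized)
    uniq = np.unique(labels)
    return np.vstack([
        np.asarray(mat[:, labels == k].mean(axis=1)).ravel() for k in uniq])


def hierarchical_group(profiles: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration on correlation distance between cluster
    mean profiles.  Returns the scipy linkage matrix (merge list + heights).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ConfigError("need at least 2 cluster profiles to group")
    return linkage(profiles, method="average", metric="correlation")


def density_by_condition(embedding_xy: np.ndarray, conditions,
                         grid_size: int = 50,
                         bw_method=None) -> dict[str, dict]:
    """Per-condition Gaussian KDE on a shared grid.

    The grid spans the joint bounding box (5% margin).  Each condition's grid
    is renormalized to integrate to exactly 1 over the grid.  A condition with
    fewer than 2 cells gets a flat density with a warning.
    Returns {condition: {"x", "y", "density"}} with density shaped
    (grid_size, grid_size), rows indexing y.
    """
    xy = np.asarray(embedding_xy, dtype=float)
    conditions = np.asarray(conditions)
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    margin = 0.05 * np.maximum(hi - lo, 1e-9)
    gx = np.linspace(lo[0] - margin[0], hi[0] + margin[0], grid_size)
    gy = np.linspace(lo[1] - margin[1], hi[1] + margin[1], grid_size)
    mx, my = np.meshgrid(gx, gy)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    out = {}
    for cond in pd.unique(conditions):
        pts = xy[conditions == cond]
        if len(pts) < 2:
            warnings.warn(f"condition {cond!r} has < 2 cells; flat density")
            dens = np.ones_like(mx)
        else:
            try:
                kde = gaussian_kde(pts.T, bw_method=bw_method)
                dens = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(mx.shape)
            except np.linalg.LinAlgError:
                warnings.warn(f"degenerate point cloud for {cond!r}; flat density")
                dens = np.ones_like(mx)
        dens = dens / (dens.sum() * cell_area)
        out[str(cond)] = {"x": gx, "y": gy, "density": dens}
    return out
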