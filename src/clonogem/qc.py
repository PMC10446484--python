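"""Quality control and normalization of UMI count matrices.

The filtering mirrors the standard droplet scRNA-seq workflow: genes detected
in too few cells are dropped first, then cells are kept only if their detected
feature count lies within a configured window and their mitochondrial UMI
fraction is below a ceiling.  Normalization is depth-scaled log1p with an
optional per-gene z-scored ("scaled") view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import AllCellsFilteredError, ConfigError
from .io_formats import GeneCellCounts


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene filtering thresholds.

    Defaults follow the common droplet QC recipe for mouse T cells: genes
    detected in < 4 cells are dropped; cells are kept with 200-2500 detected
    features and < 5% mitochondrial UMIs (mouse mitochondrial genes carry the
    lowercase ``mt-`` prefix).
    """

    min_cells_per_gene: int = 4
    min_features_per_cell: int = 200
    max_features_per_cell: int = 2500
    max_mito_fraction: float = 0.05
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_features_per_cell >= self.max_features_per_cell:
            raise ConfigError("min_features must be < max_features")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ConfigError("max_mito_fraction must lie in [0, 1]")


def mito_fraction(counts: GeneCellCounts,
                  mito_prefix: str = "mt-") -> np.ndarray:
    """Per-cell mitochondrial UMI fraction (prefix match, case-insensitive)."""
    is_mito = np.array([str(g).lower().startswith(mito_prefix.lower())
                        for g in counts.gene_ids])
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel()
    mito = np.asarray(counts.matrix[is_mito].sum(axis=0)).ravel() \
        if is_mito.any() else np.zeros(counts.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac


def filter_counts(counts: GeneCellCounts,
                  thr: QCThresholds = QCThresholds()) -> GeneCellCounts:
    """Apply gene then cell filters, one pass each.

    Genes detected (count > 0) in fewer than ``min_cells_per_gene`` cells are
    removed first.  Cells are then removed if their detected-feature count
    (computed on the gene-filtered matrix) falls outside
    ``[min_features_per_cell, max_features_per_cell]`` or their mitochondrial
    fraction — computed on the pre-gene-filter matrix, so dropping mt- genes
    cannot rescue a dying cell — is at or above ``max_mito_fraction``.
    """
    mito = mito_fraction(counts, thr.mito_prefix)
    detected = np.asarray((counts.matrix > 0).sum(axis=1)).ravel()
    gene_mask = detected >= thr.min_cells_per_gene
    sub = counts.subset(gene_mask=gene_mask)

    n_features = np.asarray((sub.matrix > 0).sum(axis=0)).ravel()
    cell_mask = ((n_features >= thr.min_features_per_cell)
                 & (n_features <= thr.max_features_per_cell)
                 & (mito < thr.max_mito_fraction))
    if not cell_mask.any():
        raise AllCellsFilteredError(
            "QC removed every cell; check thresholds against library depth")
    return sub.subset(cell_mask=cell_mask)


def lognormalize(counts: GeneCellCounts,
                 scale_factor: float = 1e4) -> sp.csr_matrix:
    """Depth-normalized log1p expression: log(1 + count / total * scale).

    Zeros stay zero, so the result is sparse.  Raises on zero-total cells
    (which cannot occur after QC).
    """
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ConfigError("zero-total cell encountered; run QC first")
    scale = scale_factor / totals
    mat = (counts.matrix.astype(float) @ sp.diags(scale)).tocsr()
    mat.data = np.log1p(mat.data)
    return mat


def scale_genes(normalized: sp.spmatrix, clip_max: float = 10.0) -> np.ndarray:
    """Per-gene z-score of the normalized matrix, clipped at ``+clip_max``.

    Zero-variance genes scale to 0 everywhere.  Returns a dense genes x cells
    array (z-scoring destroys sparsity).
    """
    dense = np.asarray(sp.csr_matrix(normalized).todense(), dtype=float)
    mu = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (dense - mu) / sd, 0.0)
    return np.minimum(z, clip_max)


def select_hvg(counts_matrix, n_hvg: int = 2000,
               loess_frac: float = 0.3) -> np.ndarray:
    """Rank genes by standardized variance and return the top ``n_hvg`` indices.

    Follows the variance-stabilizing recipe: fit a trend of log10 variance on
    log10 mean over genes (lowess; quadratic polynomial fallback when too few
    positive genes), standardize each gene's counts by the trend-expected
    standard deviation with values clipped at sqrt(n_cells), and rank by the
    variance of the clipped standardized values.  Constant genes rank last.
    """
    mat = sp.csr_matrix(counts_matrix).astype(float)
    G, N = mat.shape
    if n_hvg > G:
        warnings.warn(f"n_hvg={n_hvg} exceeds gene count {G}; capped")
        n_hvg = G
    mean = np.asarray(mat.mean(axis=1)).ravel()
    sq = mat.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0) * N / max(N - 1, 1)

    ok = (mean > 0) & (var > 0)
    expected_sd = np.zeros(G)
    if ok.sum() >= 3:
        lx, ly = np.log10(mean[ok]), np.log10(var[ok])
        if ok.sum() >= 30:
            from statsmodels.nonparametric.smoothers_lowess import lowess
            fit = lowess(ly, lx, frac=loess_frac, return_sorted=False)
        else:
            fit = np.polyval(np.polyfit(lx, ly, min(2, ok.sum() - 1)), lx)
        expected_sd[ok] = np.sqrt(10.0 ** fit)
    else:
        expected_sd[ok] = np.sqrt(var[ok])

    std_var = np.zeros(G)
    clip = np.sqrt(N)
    dense = np.asarray(mat.todense())
    for gi in np.flatnonzero(ok):
        z = (dense[gi] - mean[gi]) / expected_sd[gi]
        z = np.clip(z, -clip, clip)
        std_var[gi] = z.var(ddof=1) if N > 1 else 0.0
    order = np.lexsort((np.arange(G), -std_var))
    return order[:n_hvg]
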