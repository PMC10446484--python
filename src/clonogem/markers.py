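"""One-vs-rest marker gene detection.

Per cluster, each gene is tested with the shared Wilcoxon rank-sum kernel on
log-normalized expression; the effect size is the log2 ratio of depth-scaled
mean expression (expm1 of the log-normalized values, the usual convention).
P-values are Benjamini-Hochberg adjusted within each cluster.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .stats import bh_adjust, rank_sum_matrix

MIN_CELLS_PER_GROUP = 3


def find_markers(normalized: sp.spmatrix, labels, gene_ids,
                 min_cells: int = MIN_CELLS_PER_GROUP) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table.

    Returns a DataFrame with one row per (gene, cluster): ``log2_fold_change``
    = log2((mean expm1 in-cluster + 1) / (mean expm1 rest + 1)), raw
    ``p_value`` and BH ``adjusted_p``.  Clusters with fewer than ``min_cells``
    cells are skipped with a warning.
    """
    labels = np.asarray(labels)
    dense = np.asarray(sp.csr_matrix(normalized).todense(), dtype=float)
    expm1 = np.expm1(dense)
    gene_ids = np.asarray(gene_ids)
    frames = []
    for k in np.unique(labels):
        in_k = labels == k
        if in_k.sum() < min_cells or (~in_k).sum() < min_cells:
            warnings.warn(f"cluster {k} has < {min_cells} cells; skipped")
            continue
        mean_in = expm1[:, in_k].mean(axis=1)
        mean_out = expm1[:, ~in_k].mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        pvals = rank_sum_matrix(dense, in_k)
        frames.append(pd.DataFrame({
            "gene": gene_ids,
            "cluster_id": k,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "adjusted_p": bh_adjust(pvals),
        }))
    if not frames:
        return pd.DataFrame(columns=["gene", "cluster_id", "log2_fold_change",
                                     "p_value", "adjusted_p"])
    return pd.concat(frames, ignore_index=True)


def top_markers(marker_table: pd.DataFrame, alpha: float = 0.05,
                n: int = 1) -> pd.DataFrame:
    """Top marker(s) per cluster: max log2 fold change among adjusted_p < alpha."""
    sig = marker_table[marker_table["adjusted_p"] < alpha]
    return (sig.sort_values(["cluster_id", "log2_fold_change"],
                            ascending=[True, False])
            .groupby("cluster_id", sort=True).head(n).reset_index(drop=True))
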