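"""Shared statistical kernels.

The Wilcoxon rank-sum (Mann-Whitney) test is used in three places in the
pipeline: marker-gene detection, differential regulon activity, and
differential gene-expression-module testing.  All three call the same kernel,
:func:`rank_sum_test`, which uses an exact enumeration of the permutation
distribution when both groups are small and a tie-corrected,
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import NamedTuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

#: Largest per-group size at which the exact permutation distribution is used.
EXACT_MAX = 10


class RankSumResult(NamedTuple):
    statistic: float  # rank sum of the first sample
    p_value: float
    method: str  # "exact" or "asymptotic"


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p for the rank-sum of ``x`` by full enumeration.

    Enumerates every way of assigning the pooled observations (ties kept) to
    the two groups, computes the rank-sum distribution, and returns
    ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks for ties
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    n = len(pooled)
    idx_combos = np.array(list(combinations(range(n), n1)))
    sums = ranks[idx_combos].sum(axis=1)
    total = comb(n, n1)
    eps = 1e-9
    p_le = np.count_nonzero(sums <= w_obs + eps) / total
    p_ge = np.count_nonzero(sums >= w_obs - eps) / total
    return float(w_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_test(x, y, exact_max: int = EXACT_MAX) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Parameters
    ----------
    x, y
        The two samples.
    exact_max
        Exact enumeration is used when ``len(x) <= exact_max`` and
        ``len(y) <= exact_max``; otherwise the tie-corrected normal
        approximation with continuity correction.

    Returns
    -------
    RankSumResult with the rank sum of ``x``, the two-sided p-value, and the
    method used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("rank_sum_test requires two non-empty samples")
    w = float(sps.rankdata(np.concatenate([x, y]))[: x.size].sum())
    if np.ptp(np.concatenate([x, y])) == 0:
        # all observations identical: no evidence either way
        return RankSumResult(w, 1.0, "degenerate")
    if x.size <= exact_max and y.size <= exact_max:
        w, p = _exact_ranksum_p(x, y)
        return RankSumResult(w, p, "exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return RankSumResult(w, float(res.pvalue), "asymptotic")


def rank_sum_matrix(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected rank-sum p-values, one row of ``values`` each.

    ``values`` is a features x cells array; ``in_group`` a boolean mask over
    cells.  Equivalent to calling :func:`rank_sum_test` in asymptotic mode on
    every row, but in a single vectorized pass.  Rows with zero range return
    p = 1.
    """
    in_group = np.asarray(in_group, dtype=bool)
    x = values[:, in_group]
    y = values[:, ~in_group]
    const = np.ptp(values, axis=1) == 0
    pvals = np.ones(values.shape[0])
    if (~const).any():
        res = sps.mannwhitneyu(x[~const], y[~const], alternative="two-sided",
                               method="asymptotic", use_continuity=True,
                               axis=1)
        pvals[~const] = res.pvalue
    return pvals


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def proportion_z_test(k: int, n: int, p0: float) -> tuple[float, float]:
    """One-proportion z test of H0: true proportion equals ``p0``.

    z = (k/n - p0) / sqrt(p0 (1 - p0) / n); two-sided p = 2 (1 - Phi(|z|)).
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    if not 0 < p0 < 1:
        raise ConfigError("p0 must lie strictly between 0 and 1")
    if not 0 <= k <= n:
        raise ConfigError("k must lie in [0, n]")
    z = (k / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
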