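"""Shared statistical primitives.

Small, well-specified building blocks used across the marker, population and
enrichment modules: a two-sided Wilcoxon rank-sum test (exact by enumeration
for small groups, normal approximation with tie correction otherwise), the
Tippett minimum-p combination, p-value adjustment, and the t-based upper
confidence limit used by the cluster-expansion statistic.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "rank_sum_matrix",
    "RankSumScan",
    "tippett_combine",
    "bonferroni_adjust",
    "bh_adjust",
    "t_upper_limit",
]

#: largest per-group size for which the exact enumeration branch is used
EXACT_MAX = 10


def _ranksum_moments(ranks: np.ndarray, n1: int, n2: int) -> tuple[float, float]:
    """Mean and variance of the group-1 rank sum under the null, tie-corrected."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    # tie correction: sum over tie groups of (t^3 - t)
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts.astype(np.float64) ** 3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return mu, var


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max: int = EXACT_MAX) -> float:
    """Two-sided Wilcoxon rank-sum p-value for samples ``x`` vs ``y``.

    When both groups have at most ``exact_max`` observations the null
    distribution of the rank sum is enumerated over all assignments of the
    pooled values (ties handled exactly); otherwise a normal approximation
    with tie-corrected variance is used.  The two-sided p-value is
    ``P(|W - E[W]| >= |w_obs - E[W]|)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    mu, var = _ranksum_moments(ranks, n1, n2)

    if n1 <= exact_max and n2 <= exact_max:
        dev = abs(w_obs - mu) - 1e-9
        total = comb(n1 + n2, n1)
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= dev:
                hits += 1
        return hits / total

    if var <= 0:  # all values tied
        return 1.0
    z = (w_obs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


class RankSumScan:
    """Reusable rank-sum scan over the columns of a cells x genes matrix.

    Ranks and tie corrections are computed once; ``pvalues`` can then be
    called with different group masks (e.g. one per cluster) cheaply.
    Normal approximation with tie-corrected variance, two-sided.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        self.n = values.shape[0]
        self.ranks = stats.rankdata(values, axis=0)
        tie_term = np.empty(values.shape[1])
        sorted_vals = np.sort(values, axis=0)
        for j in range(values.shape[1]):
            col = sorted_vals[:, j]
            boundaries = np.flatnonzero(np.diff(col) != 0)
            counts = np.diff(np.concatenate([[0], boundaries + 1, [self.n]])).astype(np.float64)
            tie_term[j] = np.sum(counts ** 3 - counts)
        self.tie_term = tie_term

    def pvalues(self, in_mask: np.ndarray) -> np.ndarray:
        in_mask = np.asarray(in_mask, dtype=bool)
        n1 = int(in_mask.sum())
        n2 = self.n - n1
        if n1 == 0 or n2 == 0:
            raise ValueError("both groups must be non-empty")
        n = self.n
        w = self.ranks[in_mask].sum(axis=0)
        mu = n1 * (n + 1) / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - self.tie_term / (n * (n - 1)))
        p = np.ones_like(w)
        ok = var > 0
        z = (w[ok] - mu) / np.sqrt(var[ok])
        p[ok] = 2.0 * stats.norm.sf(np.abs(z))
        return np.minimum(p, 1.0)


def rank_sum_matrix(values: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Vectorized normal-approximation rank-sum over columns of ``values``."""
    return RankSumScan(values).pvalues(in_mask)


def tippett_combine(p_values) -> float:
    """Minimum-p (Tippett) combination: ``1 - (1 - min p)^k``."""
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        raise ValueError("cannot combine an empty set of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(1.0 - (1.0 - p.min()) ** p.size)


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment across the given family, clipped at 1."""
    p = np.asarray(p, dtype=np.float64)
    return np.minimum(p * p.size, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    if method == "bonferroni":
        return bonferroni_adjust(p)
    if method in ("bh", "fdr_bh"):
        return bh_adjust(p)
    raise ValueError(f"unknown adjustment method: {method!r}")


def t_upper_limit(folds: np.ndarray, level: float = 0.95) -> float:
    """Upper bound of the two-sided t confidence interval for the mean fold.

    ``mean + t_{(1+level)/2, n-1} * sd / sqrt(n)`` with the sample SD.
    """
    folds = np.asarray(folds, dtype=np.float64)
    n = folds.size
    if n < 2:
        raise ValueError("need at least two groups for a confidence interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mean = float(folds.mean())
    sd = float(folds.std(ddof=1))
    tcrit = float(stats.t.ppf((1 + level) / 2.0, n - 1))
    return mean + tcrit * sd / np.sqrt(n)
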