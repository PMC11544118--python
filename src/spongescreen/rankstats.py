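"""Rank-based statistics shared by all screening stages.

Implements tie-aware ranking, Spearman correlation with a t-approximation
p-value (exact permutation enumeration at small n), the Wilcoxon rank-sum
and signed-rank tests, the Kruskal-Wallis test and Benjamini-Hochberg FDR
adjustment.  Approximate modes use normal / chi-square reference
distributions with tie-corrected variances; exact modes enumerate the null
distribution of the statistic and report the two-sided extremity
probability P(|T - E[T]| >= |t - E[T]|).  All p-values are two-sided.

The module is pure computation: no file I/O, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "TestResult",
    "rank_with_ties",
    "spearman",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "bh_adjust",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with its two-sided p-value.

    ``rho`` is NaN and ``degenerate`` is True when either vector is
    constant after pairwise missing-value removal; a degenerate result is
    never silently reported as rho = 0.
    """

    rho: float
    p: float
    n: int
    degenerate: bool = False
    method: str = "t-approx"


@dataclass(frozen=True)
class TestResult:
    """A rank-test outcome: statistic, two-sided p and the method used."""

    statistic: float
    p: float
    method: str


def rank_with_ties(values) -> np.ndarray:
    """Average ranks of ``values``; ties share the mean of their ranks."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    if np.isnan(arr).any():
        raise ValueError("rank_with_ties does not accept missing values")
    return sps.rankdata(arr, method="average")


def _tie_correction_sum(ranks: np.ndarray) -> float:
    """sum over tie groups of t^3 - t (the usual tie-correction term)."""
    _, counts = np.unique(ranks, return_counts=True)
    counts = counts[counts > 1].astype(float)
    return float(np.sum(counts**3 - counts))


# ---------------------------------------------------------------------------
# Spearman correlation


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = rank_with_ties(x)
    ry = rank_with_ties(y)
    sx = rx.std()
    sy = ry.std()
    if sx < _EPS or sy < _EPS:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact: bool | None = None) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Pairs with a missing value in either vector are removed first.  The
    p-value comes from the t-approximation t = rho*sqrt((n-2)/(1-rho^2))
    on n-2 degrees of freedom; for n <= 8 (or when ``exact=True``) the
    exact permutation distribution over all n! rank assignments is
    enumerated instead.  A constant vector yields a degenerate result
    with rho = NaN and p = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rho = _spearman_rho(x, y)
    if np.isnan(rho):
        return CorrelationResult(rho=np.nan, p=np.nan, n=n, degenerate=True,
                                 method="degenerate")
    if exact is None:
        exact = n <= 8
    if exact:
        if n > 8:
            raise ValueError("exact permutation p supported only for n <= 8")
        # rho under permutation is a dot product of the fixed centered,
        # unit-norm rank vectors, so the full n! enumeration vectorises
        rx = rank_with_ties(x)
        ry = rank_with_ties(y)
        a = (rx - rx.mean()) / np.linalg.norm(rx - rx.mean())
        b = (ry - ry.mean()) / np.linalg.norm(ry - ry.mean())
        perms = np.array(list(permutations(range(n))))
        null_rho = b[perms] @ a
        p = float(np.mean(np.abs(null_rho) >= abs(rho) - 1e-12))
        return CorrelationResult(rho=rho, p=p, n=n, method="exact-perm")
    if abs(rho) >= 1.0 - _EPS:
        return CorrelationResult(rho=rho, p=0.0, n=n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho=rho, p=float(min(p, 1.0)), n=n)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney form on rank sums)


def _exact_two_sided_p(null_values: np.ndarray, observed: float) -> float:
    """P(|T - E| >= |t - E|) under the enumerated null."""
    mean = null_values.mean()
    dev = abs(observed - mean)
    return float(np.mean(np.abs(null_values - mean) >= dev - 1e-9))


def wilcoxon_rank_sum(a, b, continuity: bool = True,
                      exact: bool | None = None) -> TestResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    The statistic is W, the rank sum of the first sample in the pooled
    ranking.  For n_a + n_b <= 12 (default) the null distribution is
    enumerated over all C(n, n_a) assignments of the pooled (tie-averaged)
    ranks; otherwise a normal approximation with tie-corrected variance
    and, optionally, a 0.5 continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rank_with_ties(pooled)
    na, n = int(a.size), int(pooled.size)
    w = float(ranks[:na].sum())
    if np.ptp(pooled) < _EPS:
        return TestResult(statistic=w, p=1.0, method="rank-sum-degenerate")
    if exact is None:
        exact = n <= 12
    if exact:
        sums = np.array([ranks[list(idx)].sum()
                         for idx in combinations(range(n), na)])
        return TestResult(statistic=w, p=_exact_two_sided_p(sums, w),
                          method="rank-sum-exact")
    nb = n - na
    mean = na * (n + 1) / 2.0
    tie_sum = _tie_correction_sum(ranks)
    var = na * nb / 12.0 * ((n + 1) - tie_sum / (n * (n - 1.0)))
    if var < _EPS:
        return TestResult(statistic=w, p=1.0, method="rank-sum-degenerate")
    dev = abs(w - mean)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / np.sqrt(var)
    return TestResult(statistic=w, p=float(min(2.0 * sps.norm.sf(z), 1.0)),
                      method="rank-sum-normal")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(paired_a, paired_b, exact: bool | None = None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on matched pairs.

    Zero differences are dropped (Wilcoxon convention).  V is the sum of
    the ranks of positive differences.  Exact enumeration over all 2^m
    sign assignments is used for m <= 12 non-zero pairs, else a normal
    approximation with tie-corrected variance.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[np.abs(d) > _EPS]
    m = int(d.size)
    if m == 0:
        return TestResult(statistic=0.0, p=1.0, method="signed-rank-degenerate")
    ranks = rank_with_ties(np.abs(d))
    v = float(ranks[d > 0].sum())
    if exact is None:
        exact = m <= 12
    if exact:
        signs = np.array(np.meshgrid(*([[0, 1]] * m), indexing="ij"))
        signs = signs.reshape(m, -1).T  # 2^m x m matrix of sign patterns
        null_v = signs @ ranks
        return TestResult(statistic=v, p=_exact_two_sided_p(null_v, v),
                          method="signed-rank-exact")
    mean = m * (m + 1) / 4.0
    tie_sum = _tie_correction_sum(ranks)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_sum / 48.0
    if var < _EPS:
        return TestResult(statistic=v, p=1.0, method="signed-rank-degenerate")
    z = (v - mean) / np.sqrt(var)
    return TestResult(statistic=v, p=float(min(2.0 * sps.norm.sf(abs(z)), 1.0)),
                      method="signed-rank-normal")


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across k >= 2 groups (chi-square, k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n = int(pooled.size)
    if n < 3:
        raise ValueError("need total n >= 3")
    ranks = rank_with_ties(pooled)
    if np.ptp(pooled) < _EPS:
        return TestResult(statistic=0.0, p=1.0, method="kruskal-wallis")
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        start += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie_sum = _tie_correction_sum(ranks)
    correction = 1.0 - tie_sum / (n**3 - n)
    if correction < _EPS:
        return TestResult(statistic=0.0, p=1.0, method="kruskal-wallis")
    h /= correction
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return TestResult(statistic=h, p=p, method="kruskal-wallis")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
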