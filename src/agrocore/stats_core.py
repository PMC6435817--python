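"""Shared statistical primitives.

Rank correlation, rank-sum tests, the paired t test, Benjamini-Hochberg FDR,
ordinary least squares on a single predictor, and the Z-score transform.
All tests are two-sided.  Undefined statistics (constant inputs, zero paired
differences) are returned as NaN with ``is_na`` set rather than raised, so
callers can classify them as non-significant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "spearman",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "paired_t",
    "bh_fdr",
    "linear_regression",
    "zscore",
]

# Below this sample size the Spearman p-value is computed by exhaustive
# permutation of one rank vector; above, by the t approximation.
SPEARMAN_EXACT_N_MAX = 9
# Rank-sum test switches from the exact null to the normal approximation
# (with tie correction) above this total sample size.
WILCOXON_EXACT_N_MAX = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``is_na`` marks statistics that are undefined for the given input
    (e.g. a paired t with all differences zero); downstream classification
    treats NA as non-significant.
    """

    statistic: float
    p_value: float
    n_used: int
    method: str
    is_na: bool = False

    def __post_init__(self) -> None:
        if not self.is_na and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _drop_pairwise_na(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with ties handled by average ranks.

    Returns ``(rho, p)``.  For n <= 9 the p-value is exact (enumeration of
    all permutations of one rank vector); otherwise it comes from the
    t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``.  A constant input
    vector makes rho undefined: ``(nan, nan)`` is returned.
    """
    x, y = _drop_pairwise_na(x, y)
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if n <= SPEARMAN_EXACT_N_MAX:
        perms = _all_permutations(n)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
        null = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return (rho, min(p, 1.0))


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Exact null distribution for total n <= 20 without ties; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n = a.size + b.size
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < n
    if np.ptp(pooled) == 0:
        return TestResult(math.nan, math.nan, n, "wilcoxon", is_na=True)
    method = "exact" if (n <= WILCOXON_EXACT_N_MAX and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), n, "wilcoxon")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across two or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    n = int(sum(g.size for g in groups))
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult(math.nan, math.nan, n, "kruskal", is_na=True)
    stat, p = sps.kruskal(*groups)
    return TestResult(float(stat), float(p), n, "kruskal")


def paired_t(a, b) -> TestResult:
    """Two-sided paired t test: t = mean(d) / (sd(d)/sqrt(n)), d = a - b.

    All-zero or constant differences leave the statistic undefined (sd(d)=0);
    the result is NA-flagged.
    """
    a, b = _drop_pairwise_na(a, b)
    n = a.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    # sd exactly zero, or zero up to float cancellation in a constant shift
    if sd == 0 or sd < 1e-12 * max(abs(d.mean()), np.abs(d).max()):
        return TestResult(math.nan, math.nan, n, "paired_t", is_na=True)
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return TestResult(t, p, n, "paired_t")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.  Empty input -> empty output."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def linear_regression(x, y) -> tuple[float, float, float, float]:
    """OLS of y on x: returns (slope, intercept, R^2, p_slope)."""
    x, y = _drop_pairwise_na(x, y)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample (n-1) sd 1.  Constant input -> error."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot Z-score a constant vector (sd = 0)")
    return (v - v.mean()) / sd
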