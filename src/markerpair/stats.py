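"""Univariate statistics backing the response-side report.

Wilcoxon rank-sum, Spearman correlation, Fisher's exact 2x2 independence
test, exact binomial confidence intervals for response rates, and p-value
adjustment (Bonferroni, Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_used: int
    estimate: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RateCI:
    successes: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def to_dict(self) -> dict:
        return asdict(self)


def _clean(x):
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def wilcoxon_rank_sum(group_a, group_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when both groups have <= 25 observations and no
    ties across the pooled sample; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum: both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = a.size <= 25 and b.size <= 25 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon_exact" if exact else "wilcoxon_normal_approx",
                      int(a.size + b.size))


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("spearman_corr: need at least 3 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(np.nan, np.nan, "spearman", n, estimate=np.nan, degenerate=True)
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman", n, estimate=float(rho))


def fisher_exact_2x2(counts) -> TestResult:
    """Fisher's exact test on a 2x2 table; two-sided hypergeometric rule.

    Estimate is the sample odds ratio, with a Haldane-Anscombe +0.5 applied
    to every cell iff any cell is zero.  A zero margin makes the test
    degenerate: p = 1.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact_2x2: need a 2x2 table of non-negative counts")
    n = int(t.sum())
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    (a, b), (c, d) = t
    if b * c == 0 and a * d == 0:
        orr = np.nan
    elif min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    if (row == 0).any() or (col == 0).any():
        return TestResult(np.nan, 1.0, "fisher_exact", n, estimate=orr, degenerate=True)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(orr) if np.isfinite(orr) else np.nan, float(p),
                      "fisher_exact", n, estimate=float(orr) if np.isfinite(orr) else np.nan)


def binomial_ci(successes: int, n: int, level: float = 0.95,
                method: str = "clopper-pearson") -> RateCI:
    """Exact (Clopper-Pearson) or Wilson confidence interval for a rate."""
    if n < 1:
        raise ValueError("binomial_ci: n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("binomial_ci: successes out of range")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    return RateCI(int(successes), int(n), successes / n,
                  float(max(lo, 0.0)), float(min(hi, 1.0)), level)


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m*p)."""
    if not 0 <= p <= 1:
        raise ValueError("p out of [0,1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values out of [0,1]")
    return multipletests(p, method="fdr_bh")[1]
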