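"""Shared statistical testing policy.

The study compares small groups of plasma samples: Student's t-test whenever
either group has fewer than five samples, otherwise the Wilcoxon rank-sum
test.  One-tailed directions are always explicit arguments — nothing here
infers a direction from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str
    n_a: int
    n_b: int


def choose_test(n_a: int, n_b: int) -> str:
    """Return ``"t"`` if either group has fewer than five samples, else ``"wilcoxon"``."""
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >= 2 samples, got ({n_a}, {n_b})")
    return "t" if min(n_a, n_b) < 5 else "wilcoxon"


def t_test(a, b, alternative: str = "two-sided") -> TestResult:
    """Student's (pooled-variance) two-sample t-test.

    Degenerate input with zero variance in both groups and equal means gives
    p = 1 rather than NaN.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, alternative, "t", a.size, b.size)
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, "t", a.size, b.size)


def welch_t_test(a, b, alternative: str = "two-sided") -> TestResult:
    """Welch (unequal-variance) two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, "welch", a.size, b.size)


def wilcoxon_rank_sum(a, b, alternative: str = "less") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration is used for small tie-free samples (n_a + n_b <= 12);
    otherwise the normal approximation with tie correction.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p = 1")
        return TestResult(np.nan, 1.0, alternative, "wilcoxon", a.size, b.size)
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, "wilcoxon", a.size, b.size)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
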