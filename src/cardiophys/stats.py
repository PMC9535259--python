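"""Group comparison and correlation machinery.

Summaries are reported as mean +/- SEM.  Comparisons use a paired t-test,
an unpaired t-test with equal (Student) or unequal (Welch) variances, and
the Mann-Whitney test; correlation is sample Pearson r with a two-sided
t-based p-value.  All p-values are two-sided.

The ``auto`` variance mode selects Welch's test when a two-sided F-test of
variance equality rejects at 0.05, and Student's pooled-variance test
otherwise; both explicit modes remain available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as sps

from .errors import AnalysisError, PairingError, ValidationError

__all__ = [
    "GroupSummary",
    "TestResult",
    "CorrelationResult",
    "mean_sem",
    "ttest_unpaired",
    "ttest_paired",
    "mann_whitney",
    "pearson_corr",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float  # sd/sqrt(n) with the n-1 denominator; NaN when n < 2
    label: str = ""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n1: int
    n2: int
    df: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError("|r| must not exceed 1")


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    return x[~np.isnan(x)]


def mean_sem(values, label: str = "") -> GroupSummary:
    """Arithmetic mean and standard error (sd with n-1 denominator over sqrt n)."""
    x = _clean(values)
    if x.size == 0:
        raise AnalysisError("mean_sem requires at least one value")
    sem = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size >= 2 else float("nan")
    return GroupSummary(n=int(x.size), mean=float(np.mean(x)), sem=sem, label=label)


def _variances_equal_f_test(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> bool:
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if v1 == 0 and v2 == 0:
        return True
    hi, lo = max(v1, v2), min(v1, v2)
    if lo == 0:
        return False
    if v1 >= v2:
        dfn, dfd = a.size - 1, b.size - 1
    else:
        dfn, dfd = b.size - 1, a.size - 1
    p = 2.0 * sps.f.sf(hi / lo, dfn, dfd)
    return min(p, 1.0) >= alpha


def ttest_unpaired(a, b, variance_mode: str = "auto") -> TestResult:
    """Two-sample t-test: Student (pooled), Welch (Satterthwaite df), or auto.

    ``auto`` falls back to Welch when an F-test of variance equality has
    p < 0.05.  When both groups have zero variance and equal means the
    result is t = 0, p = 1 by convention.
    """
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("ttest_unpaired requires n >= 2 per group")
    if variance_mode not in ("equal", "unequal", "auto"):
        raise ValidationError(f"unknown variance_mode {variance_mode!r}")
    if variance_mode == "auto":
        equal = _variances_equal_f_test(a, b)
    else:
        equal = variance_mode == "equal"
    name = "student_t" if equal else "welch_t"
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult(0.0, 1.0, name, a.size, b.size,
                              df=float(a.size + b.size - 2))
        return TestResult(math.copysign(math.inf, np.mean(a) - np.mean(b)), 0.0,
                          name, a.size, b.size, df=float(a.size + b.size - 2))
    res = sps.ttest_ind(a, b, equal_var=equal)
    return TestResult(float(res.statistic), float(res.pvalue), name,
                      int(a.size), int(b.size), df=float(res.df))


def ttest_paired(pre, post) -> TestResult:
    """Paired t-test (one-sample t on the post-pre differences)."""
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size != post.size:
        raise PairingError("paired t-test requires matched, equal-length samples")
    keep = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[keep], post[keep]
    if pre.size < 2:
        raise AnalysisError("ttest_paired requires n >= 2 pairs")
    d = post - pre
    if np.var(d, ddof=1) == 0:
        if np.all(d == 0):
            return TestResult(0.0, 1.0, "paired_t", pre.size, pre.size,
                              df=float(pre.size - 1))
        return TestResult(math.copysign(math.inf, d[0]), 0.0, "paired_t",
                          pre.size, pre.size, df=float(pre.size - 1))
    res = sps.ttest_rel(post, pre)
    return TestResult(float(res.statistic), float(res.pvalue), "paired_t",
                      int(pre.size), int(pre.size), df=float(pre.size - 1))


def mann_whitney(a, b) -> TestResult:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when n1 + n2 <= 12 and the data are tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a, b = _clean(a), _clean(b)
    if a.size < 3 or b.size < 3:
        raise AnalysisError("mann_whitney requires n >= 3 per group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"mann_whitney_{method}", int(a.size), int(b.size))


def pearson_corr(x, y) -> CorrelationResult:
    """Sample Pearson correlation, p from t = r*sqrt((n-2)/(1-r^2)), two-sided."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise PairingError("pearson_corr requires equal-length samples")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise AnalysisError("pearson_corr requires n >= 3 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise AnalysisError("pearson_corr is undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=int(x.size))
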