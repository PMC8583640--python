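"""Nonparametric statistical toolbox for cohort tables.

Thin, validated wrappers around scipy's rank statistics, with the
conventions fixed once: two-sided tests, mid-ranks for ties, an exact
Mann-Whitney null for small tie-free samples (n <= 20 per group) and the
tie-corrected normal approximation otherwise.  Every result records which
path was taken in its ``method`` label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["TestResult", "rank_sum_compare", "spearman_rho", "ks_normality", "stats_report"]

EXACT_N_MAX = 20  # per-group switch point between the exact and normal MW null


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _clean(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def rank_sum_compare(values_a, values_b) -> TestResult:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    Uses the exact null distribution when both groups have n <= 20 and
    there are no ties, and the tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    a = _clean(values_a, "sample a")
    b = _clean(values_b, "sample b")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    label = (
        f"Mann-Whitney U, two-sided, {method} null"
        + (", mid-ranked ties" if has_ties else "")
    )
    return TestResult(float(res.statistic), float(res.pvalue), label, (a.size, b.size))


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with average-rank tie handling.

    A constant input leaves the rank correlation undefined; that is raised
    explicitly rather than silently reported as zero.
    """
    xa = _clean(x, "x")
    ya = _clean(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValueError("spearman_rho requires at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("rank correlation undefined for a constant input")
    res = stats.spearmanr(xa, ya)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        "Spearman rank correlation, average ranks",
        (xa.size,),
    )


def ks_normality(values) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and sd, so the reported
    p-value is conservative (the Lilliefors correction is not applied);
    this caveat is logged and recorded in the method label.
    """
    arr = _clean(values, "sample")
    if arr.size < 5:
        raise ValueError("ks_normality requires at least 5 observations")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise ValueError("normality test undefined for a constant sample")
    logger.debug(
        "KS normality uses estimated parameters; p-values are conservative "
        "(Lilliefors caveat)"
    )
    res = stats.kstest(arr, "norm", args=(float(np.mean(arr)), sd))
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        "one-sample KS vs normal(sample mean, sample sd); Lilliefors caveat",
        (arr.size,),
    )


def stats_report(rows) -> pd.DataFrame:
    """Assemble (variable, grouping, TestResult) triples into a flat table."""
    out = []
    for variable, grouping, result in rows:
        out.append(
            {
                "variable": variable,
                "grouping": grouping,
                "method": result.method,
                "statistic": result.statistic,
                "p": result.p_value,
            }
        )
    return pd.DataFrame(out)
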