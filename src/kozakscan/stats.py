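"""Comparison tests shared by the cohort, conservation, and metagene stages.

Three tests cover all the pairwise comparisons: a 2x2 chi-squared without
continuity correction (frame-0 contrasts), a two-sided Mann-Whitney rank-sum
test (distances, ORF lengths, conservation scores, window densities), and
Welch's unequal-variance t-test (context strengths).  The rank-sum test uses
the exact null distribution when both samples have at most 50 observations
and no ties are present, and otherwise the normal approximation with tie
correction and no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 50


@dataclass
class ComparisonResult:
    test: str  # chi2_2x2 | rank_sum_two_sided | welch_t
    statistic: float
    p_value: float
    n1: int
    n2: int
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Two-sided Mann-Whitney U test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("rank-sum test requires at least one observation per side")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # fully degenerate: no evidence against the null
        return ComparisonResult(
            "rank_sum_two_sided", len(x) * len(y) / 2.0, 1.0, len(x), len(y)
        )
    has_ties = np.unique(pooled).size < pooled.size
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult("rank_sum_two_sided", float(res.statistic), p, len(x), len(y))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Welch's unequal-variance two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch test requires at least two observations per side")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(x) == np.mean(y):
            return ComparisonResult("welch_t", 0.0, 1.0, len(x), len(y))
        return ComparisonResult(
            "welch_t", np.inf if np.mean(x) > np.mean(y) else -np.inf, 0.0,
            len(x), len(y), warning="zero variance in both samples",
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return ComparisonResult("welch_t", float(res.statistic), float(res.pvalue), len(x), len(y))


def chi2_2x2(table: Sequence[Sequence[float]]) -> ComparisonResult:
    """2x2 chi-squared test of independence without continuity correction.

    Rows are groups, columns are outcome counts.  A warning is flagged when
    any expected cell count falls below 5.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if arr.sum() == 0:
        raise ValueError("empty contingency table")
    res = sps.chi2_contingency(arr, correction=False)
    warning = None
    if (res.expected_freq < 5).any():
        warning = "expected cell count below 5"
    n1, n2 = int(arr[0].sum()), int(arr[1].sum())
    return ComparisonResult("chi2_2x2", float(res.statistic), float(res.pvalue), n1, n2, warning)


def comparison_to_dict(result: ComparisonResult) -> dict:
    return {
        "test": result.test,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "n1": result.n1,
        "n2": result.n2,
        "warning": result.warning,
    }
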