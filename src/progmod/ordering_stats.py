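"""Rank-based comparison of event orderings within and between groups.

Positions of biomarkers across thinned MCMC samples or bootstrap replicates
are ordinal data, so comparisons use non-parametric tests: one-tailed
Wilcoxon signed-rank for "does biomarker i become abnormal before j" within
a group, and two-tailed Mann-Whitney U for "does this biomarker sit at a
different position in the two groups", with Bonferroni control over each
test family. Small positions mean early events; "i before j" is the
alternative median(pos_i - pos_j) < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, wilcoxon

__all__ = [
    "OrderTestResult",
    "within_group_order_test",
    "between_group_position_test",
    "bonferroni_control",
]


@dataclass(frozen=True)
class OrderTestResult:
    statistic: float
    p_value: float
    degenerate: bool = False
    effect_size: float | None = None


def within_group_order_test(pos_i, pos_j) -> OrderTestResult:
    """One-tailed Wilcoxon signed-rank: does event i precede event j?

    ``pos_i`` and ``pos_j`` are paired position vectors (one entry per
    posterior sample / replicate). Zero differences are discarded (the
    standard convention); exact small-sample p-values are used where scipy's
    auto mode permits. If every difference is zero the test is degenerate
    and p = 1 is returned.
    """
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    if pos_i.shape != pos_j.shape:
        raise ValueError("position vectors must have equal length")
    if len(pos_i) < 5:
        raise ValueError("need at least 5 paired samples")
    d = pos_i - pos_j
    if np.all(d == 0):
        return OrderTestResult(statistic=np.nan, p_value=1.0, degenerate=True)
    stat, p = wilcoxon(pos_i, pos_j, alternative="less",
                       zero_method="wilcox", method="auto", correction=True)
    return OrderTestResult(statistic=float(stat), p_value=float(p))


def between_group_position_test(pos_group1, pos_group2) -> OrderTestResult:
    """Two-tailed Mann-Whitney U with tie correction, plus rank-biserial
    effect size, for one biomarker's positions in two groups."""
    x = np.asarray(pos_group1, dtype=float)
    y = np.asarray(pos_group2, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("need at least 5 samples per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return OrderTestResult(statistic=np.nan, p_value=1.0, degenerate=True,
                               effect_size=0.0)
    u, p = mannwhitneyu(x, y, alternative="two-sided")
    rank_biserial = 2.0 * u / (len(x) * len(y)) - 1.0
    return OrderTestResult(statistic=float(u), p_value=float(p),
                           effect_size=float(rank_biserial))


def bonferroni_control(p_values, m: int | None = None,
                       alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Bonferroni decisions: reject where p < alpha / m.

    ``m`` defaults to the number of p-values and must not be smaller than
    it (the family may be larger when some tests were degenerate). Returns
    (boolean rejection vector, corrected threshold).
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    threshold = alpha / m if m > 0 else alpha
    return p < threshold, threshold
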