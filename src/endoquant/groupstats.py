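"""Condition-level statistics: mean +/- s.e.m., unpaired two-tailed
Student's t-tests, and significance stars.

The unit of analysis (cells, experiments, synaptic profiles) differs per
measurement, so callers pass per-unit values explicitly.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidConfigError

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class SummaryStats:
    mean: float
    sem: float
    n: int
    sem_defined: bool = True


@dataclass
class GroupComparison:
    metric: str
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    stars: str
    equal_var: bool = True


def summarize(values: Sequence[float]) -> SummaryStats:
    """Arithmetic mean and s.e.m. (sd with n-1 over sqrt(n)).

    A single value has an undefined s.e.m.; it is reported as NaN with
    ``sem_defined=False`` rather than silently as zero.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidConfigError("cannot summarize an empty sample")
    mean = float(arr.mean())
    if arr.size == 1:
        return SummaryStats(mean, math.nan, 1, sem_defined=False)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return SummaryStats(mean, sem, int(arr.size))


def stars_for_p(p_value: float) -> str:
    """Map a p-value to the reporting convention: <0.05 *, <0.01 **, <0.001 ***."""
    for thr, stars in STAR_THRESHOLDS:
        if p_value < thr:
            return stars
    return "ns"


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    metric: str = "",
    label_a: str = "A",
    label_b: str = "B",
    equal_var: bool = True,
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of per-unit values.

    Student's equal-variance test by default; Welch's correction is
    available behind ``equal_var=False``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidConfigError("t-test needs n >= 2 in each group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    sa, sb = summarize(a), summarize(b)
    return GroupComparison(
        metric=metric, label_a=label_a, label_b=label_b,
        n_a=sa.n, n_b=sb.n, mean_a=sa.mean, mean_b=sb.mean,
        sem_a=sa.sem, sem_b=sb.sem,
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
        stars=stars_for_p(float(res.pvalue)), equal_var=equal_var,
    )
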