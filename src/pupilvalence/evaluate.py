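"""Confusion-matrix metrics and the two-condition repeated-measures F test.

The confusion matrix follows a row-per-true-class orientation in which FP
counts positive-class instances detected as negative and FN counts
negative-class instances detected as positive (so TP + FP exhausts the true
positives and FN + TN the true negatives).  Two specificity variants are
provided: TN/(TN+FN), which under this orientation is the detection rate of
the negative class, and the conventional false-alarm-based TN/(TN+FP);
both are reported side by side because they disagree whenever FP != FN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import DataError


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts (or percents) for a two-class problem.

    ``tp``: true positives detected as positive; ``fp``: true positives
    detected as negative; ``fn``: true negatives detected as positive;
    ``tn``: true negatives detected as negative.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    positive_class: str = "positive"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion-matrix entries must be nonnegative")
        if self.total == 0:
            raise DataError("confusion matrix is empty")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The same matrix with the roles of the two classes interchanged."""
        return ConfusionMatrix(
            tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp,
            positive_class=f"not-{self.positive_class}",
        )


def accuracy(c: ConfusionMatrix) -> float:
    """Percent of correctly detected instances: 100 * (TP + TN) / total."""
    return 100.0 * (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionMatrix) -> float:
    """Percent 100 * TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise DataError("sensitivity undefined: TP + FN = 0")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionMatrix) -> float:
    """Percent 100 * TN / (TN + FN): negative-class detection rate (see module doc)."""
    if c.tn + c.fn == 0:
        raise DataError("specificity undefined: TN + FN = 0")
    return 100.0 * c.tn / (c.tn + c.fn)


def specificity_standard(c: ConfusionMatrix) -> float:
    """Percent 100 * TN / (TN + FP) — the conventional definition."""
    if c.tn + c.fp == 0:
        raise DataError("specificity undefined: TN + FP = 0")
    return 100.0 * c.tn / (c.tn + c.fp)


def metrics_report(c: ConfusionMatrix) -> dict:
    """All four metrics of one confusion matrix, as a JSON-ready dict."""
    return {
        "accuracy": accuracy(c),
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "specificity_standard": specificity_standard(c),
    }


class RmAnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def rm_anova_two(cond_a, cond_b) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with two within-unit conditions.

    ``cond_a`` and ``cond_b`` are paired per-unit series (e.g. one value per
    subject under each condition).  With two levels the test has df = (1,
    n-1) and the F statistic equals the square of the paired t statistic;
    no sphericity correction is needed.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("conditions must be paired 1-D series of equal length")
    n = a.size
    if n < 2:
        raise DataError("repeated-measures ANOVA needs at least 2 units")
    data = np.stack([a, b])          # conditions x units
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_subj = 2 * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = 1, n - 1
    ms_err = ss_err / df2
    if ms_err <= 0:
        # zero within-unit error: identical conditions give F = 0, any
        # difference with no error variance is reported as infinite
        f = 0.0 if ss_cond <= 1e-300 else np.inf
    else:
        f = float(ss_cond / ms_err)
    p = float(stats.f.sf(f, df1, df2))
    return RmAnovaResult(F=f, df1=df1, df2=df2, p=p)
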