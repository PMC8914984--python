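"""Study-level quantitative machinery.

Sample-size formula, confusion-matrix accounting over a label table, the
standard binary-classification metrics, IEMG trend slope, and the paired
two-tailed t-test used to contrast IEMG slopes between conditions.

The confusion accounting uses only the last two segments of each muscle's
session: fatigue in the final segment is a true positive (non-fatigue there a
false negative), and non-fatigue in the penultimate segment is a true negative
(fatigue there a false positive).  Earlier segments contribute no counts.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .io import LabelTable, LABEL_NOT_EXAMINED
from .classifier import LABEL_FATIGUE, LABEL_NON_FATIGUE


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs to the proportion-based sample-size formula.

    ``z_crit`` is the significance criterion (1.96 for a 95% confidence level),
    ``rho`` the proportional estimate from preliminary studies, and ``d`` the
    full confidence-interval width (0.2 for a ±10% interval).
    """

    rho: float
    z_crit: float = 1.96
    d: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.rho < 1):
            raise ValueError(f"rho must lie in (0, 1), got {self.rho}")
        if self.d <= 0:
            raise ValueError("d must be positive")


class SampleSize(NamedTuple):
    raw: float
    required: int


def sample_size(p: SampleSizeParams) -> SampleSize:
    """N = 4 z^2 rho (1 - rho) / d^2, raw and rounded up to whole subjects."""
    raw = 4.0 * p.z_crit**2 * p.rho * (1.0 - p.rho) / p.d**2
    return SampleSize(raw=raw, required=math.ceil(raw))


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    """Sensitivity, specificity, positive predictive value and accuracy."""

    sensitivity: float
    specificity: float
    ppv: float
    accuracy: float


def confusion_from_labels(table: LabelTable) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from the last two segments of every usable muscle row."""
    c = ConfusionCounts()
    for row in table.usable_rows():
        labels = [l for l in row.labels if l != LABEL_NOT_EXAMINED]
        if len(labels) < 2:
            raise ValueError(f"muscle {row.muscle_id!r} has fewer than 2 labelled segments")
        last, penultimate = labels[-1], labels[-2]
        if last == LABEL_FATIGUE:
            c.tp += 1
        else:
            c.fn += 1
        if penultimate == LABEL_NON_FATIGUE:
            c.tn += 1
        else:
            c.fp += 1
    if c.total == 0:
        raise ValueError("label table has no usable rows")
    return c


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> Metrics:
    """Standard binary metrics from confusion counts (NaN on a zero denominator)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    return Metrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        ppv=_ratio(c.tp, c.tp + c.fp, "positive predictive value"),
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy"),
    )


def iemg_slope(values: Sequence[float]) -> float:
    """Ordinary least-squares slope of an IEMG series against segment index."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 points for a slope")
    return float(stats.linregress(np.arange(y.size), y).slope)


class TTestResult(NamedTuple):
    statistic: float
    p_value: float
    df: int


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Paired two-tailed t-test on the element-wise differences (df = n - 1)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal lengths")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d, d[0]):
        raise ValueError("zero variance of differences: t statistic undefined")
    res = stats.ttest_rel(x, y)
    return TTestResult(statistic=float(res.statistic), p_value=float(res.pvalue), df=x.size - 1)
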