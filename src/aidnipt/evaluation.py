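"""Confusion-matrix metrics with normal-approximation confidence intervals.

Sensitivity, specificity, PPV and NPV are reported as percentages with
two decimals and a 95% Wald interval ``p +/- 1.96 * sqrt(p(1-p)/n)``
(``n`` the metric's own denominator), capped to [0, 100].  Rounding is
half-up, so recomputation from published confusion counts reproduces
printed values exactly.  "Overall" positivity pools the three target
trisomies: a sample called positive for any of them counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "MetricWithCI", "confusion_matrix",
           "metric_with_ci", "performance_table", "METRICS"]

METRICS = ("sensitivity", "specificity", "ppv", "npv")
_Z95 = 1.96


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    """Point estimate and 95% CI, in percent rounded to 2 decimals."""

    estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 100.0):
            raise ValueError("CI must satisfy 0 <= low <= estimate <= high <= 100")

    def __str__(self) -> str:
        def fmt(x: float) -> str:
            s = f"{x:.2f}".rstrip("0").rstrip(".")
            return s
        return f"{fmt(self.estimate)} ({fmt(self.ci_low)}–{fmt(self.ci_high)})"


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_matrix(calls, truth) -> ConfusionMatrix:
    """Tally calls against truth (boolean Series/arrays aligned by index).

    With pandas Series the indices must agree (sample ids); mismatched
    ids raise.  Arrays are compared positionally.
    """
    if isinstance(calls, pd.Series) and isinstance(truth, pd.Series):
        if not calls.index.sort_values().equals(truth.index.sort_values()):
            raise ValueError("calls and truth sample ids do not match")
        truth = truth.reindex(calls.index)
    c = np.asarray(calls, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if c.shape != t.shape:
        raise ValueError("calls and truth have different lengths")
    return ConfusionMatrix(
        tp=int(np.sum(c & t)), fn=int(np.sum(~c & t)),
        fp=int(np.sum(c & ~t)), tn=int(np.sum(~c & ~t)),
    )


def metric_with_ci(cm: ConfusionMatrix, metric: str) -> MetricWithCI:
    """One metric of the confusion matrix with its 95% Wald interval."""
    pairs = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    if metric not in pairs:
        raise ValueError(f"unknown metric {metric!r}")
    num, den = pairs[metric]
    if den == 0:
        raise UndefinedMetricError(f"{metric} undefined: zero denominator")
    p = num / den
    half = _Z95 * np.sqrt(p * (1.0 - p) / den)
    return MetricWithCI(
        estimate=_round2(100.0 * p),
        ci_low=_round2(max(100.0 * (p - half), 0.0)),
        ci_high=_round2(min(100.0 * (p + half), 100.0)),
    )


def performance_table(matrices: dict[str, ConfusionMatrix]) -> pd.DataFrame:
    """One row per method: counts plus all four metrics formatted with CIs."""
    rows = []
    for name, cm in matrices.items():
        row: dict = {"method": name, "tp": cm.tp, "fn": cm.fn,
                     "fp": cm.fp, "tn": cm.tn}
        for metric in METRICS:
            try:
                row[metric] = str(metric_with_ci(cm, metric))
            except UndefinedMetricError:
                row[metric] = "n/a"
        rows.append(row)
    return pd.DataFrame(rows)
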