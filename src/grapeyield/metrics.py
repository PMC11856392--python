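"""Evaluation metrics for count regression and mask segmentation.

Count/weight accuracy: MAE and the coefficient of determination R^2
(R^2 = 1 - SS_res / SS_tot with SS_tot about the mean of the observed
values).  Segmentation accuracy: per-pixel IoU, precision, recall and F1
with the grape foreground as the positive class.  ``deviation_accuracy``
reports 100 * (1 - MAE / mean(observed)), the percentage-deviation reading
of count accuracy.

Conventions for degenerate inputs: IoU of two empty masks is 1.0 (perfect
agreement on "nothing there"); precision/recall/F1 with a zero denominator
return 0.0 and emit a :class:`DegenerateMetricWarning`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "DegenerateMetricWarning",
    "mae",
    "r_squared",
    "deviation_accuracy",
    "confusion_from_masks",
    "iou",
    "precision",
    "recall",
    "f1",
]


class DegenerateMetricWarning(UserWarning):
    """A metric denominator was zero; the conventional value 0.0 was returned."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion tallies; foreground (grape) is the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _paired(y, y_hat, min_len=1):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("observed and predicted series must have equal length")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} observations")
    return y, y_hat


def mae(y, y_hat) -> float:
    """Mean absolute error, in the units of ``y``."""
    y, y_hat = _paired(y, y_hat, min_len=1)
    return float(np.mean(np.abs(y - y_hat)))


def r_squared(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative."""
    y, y_hat = _paired(y, y_hat, min_len=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def deviation_accuracy(y, y_hat) -> float:
    """Count accuracy as percentage deviation: 100 * (1 - MAE / mean(y))."""
    y, y_hat = _paired(y, y_hat, min_len=1)
    m = float(np.mean(y))
    if m == 0.0:
        raise ValueError("deviation accuracy undefined: mean observed value is zero")
    return 100.0 * (1.0 - mae(y, y_hat) / m)


def _as_binary(arr) -> np.ndarray:
    a = np.asarray(arr)
    return a.astype(bool)


def confusion_from_masks(pred, truth) -> ConfusionCounts:
    """Per-pixel confusion counts between two binary masks."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def iou(pred, truth) -> float:
    """Intersection over union of two binary masks; empty vs empty -> 1.0."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    union = int(np.count_nonzero(p | t))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(p & t)) / union


def precision(c: ConfusionCounts) -> float:
    """tp / (tp + fp); 0.0 with a warning when nothing was predicted positive."""
    denom = c.tp + c.fp
    if denom == 0:
        warnings.warn("precision denominator is zero", DegenerateMetricWarning, stacklevel=2)
        return 0.0
    return c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """tp / (tp + fn); 0.0 with a warning when no positives exist in truth."""
    denom = c.tp + c.fn
    if denom == 0:
        warnings.warn("recall denominator is zero", DegenerateMetricWarning, stacklevel=2)
        return 0.0
    return c.tp / denom


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0.0 with a warning if undefined."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateMetricWarning)
        p, r = precision(c), recall(c)
    if p + r == 0.0:
        warnings.warn("F1 denominator is zero", DegenerateMetricWarning, stacklevel=2)
        return 0.0
    return 2.0 * p * r / (p + r)
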