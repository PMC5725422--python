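"""Confusion matrices and classification performance metrics.

2-class models are scored with accuracy, sensitivity, specificity, the
Matthews correlation coefficient and balanced accuracy from the standard
2x2 confusion matrix.  3-class models with an ``unknown`` rejection output
are scored with per-class and overall recall rates from a 3x4 matrix
(rows = actual most/less/no-DILI, columns = predicted most/less/no/unknown).

A metric whose denominator is zero is reported as ``None`` ("undefined"),
never silently coerced to 0, so aggregation over many resampling iterations
can skip such iterations with an explicit count.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_types import LESS_DILI, MOST_DILI, NO_DILI, UNKNOWN, ClassScheme, DataError

__all__ = [
    "ConfusionMatrix2",
    "ConfusionMatrix3",
    "MetricSet2",
    "RecallSet3",
    "confusion_2class",
    "metrics_2class",
    "confusion_3class",
    "recall_rates",
]


@dataclass(frozen=True)
class ConfusionMatrix2:
    """2x2 tally: positive = most-DILI by convention."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix2") -> "ConfusionMatrix2":
        return ConfusionMatrix2(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricSet2:
    """2-class metrics; a field is None when its denominator was zero."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    mcc: Optional[float]
    balanced_accuracy: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "balanced_accuracy": self.balanced_accuracy,
        }


def confusion_2class(
    predicted: Sequence[str], actual: Sequence[str], scheme: ClassScheme
) -> ConfusionMatrix2:
    """Tally a 2x2 confusion matrix from predicted and actual class labels."""
    if len(predicted) != len(actual):
        raise DataError(f"{len(predicted)} predictions vs {len(actual)} actual labels")
    pos = scheme.positive
    tp = fp = fn = tn = 0
    for p, a in zip(predicted, actual):
        if a == pos:
            if p == pos:
                tp += 1
            else:
                fn += 1
        else:
            if p == pos:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix2(tp, fp, fn, tn)


def metrics_2class(cm: ConfusionMatrix2) -> MetricSet2:
    """Accuracy, sensitivity, specificity, MCC and balanced accuracy.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); balanced
    accuracy is the mean of sensitivity and specificity.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn

    accuracy = (tp + tn) / cm.total if cm.total > 0 else None
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    specificity = tn / (tn + fp) if tn + fp > 0 else None
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den > 0 else None
    if sensitivity is not None and specificity is not None:
        balanced = (tp * (tn + fp) + tn * (tp + fn)) / (2 * (tp + fn) * (tn + fp))
    else:
        balanced = None
    return MetricSet2(accuracy, sensitivity, specificity, mcc, balanced)


# ---------------------------------------------------------------------------
# 3-class with rejection
# ---------------------------------------------------------------------------

_ACTUAL_ORDER = (MOST_DILI, LESS_DILI, NO_DILI)
_PREDICTED_ORDER = (MOST_DILI, LESS_DILI, NO_DILI, UNKNOWN)


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x4 tally; first letter = actual class (M/L/N), second = predicted
    class (M/L/N/U for unknown)."""

    mm: int
    ml: int
    mn: int
    mu: int
    lm: int
    ll: int
    ln: int
    lu: int
    nm: int
    nl: int
    nn: int
    nu: int

    def __post_init__(self) -> None:
        if min(self.as_array().ravel()) < 0:
            raise DataError("confusion cells must be nonnegative")

    def as_array(self) -> np.ndarray:
        """Rows = actual (M, L, N); columns = predicted (M, L, N, U)."""
        return np.array(
            [
                [self.mm, self.ml, self.mn, self.mu],
                [self.lm, self.ll, self.ln, self.lu],
                [self.nm, self.nl, self.nn, self.nu],
            ],
            dtype=int,
        )

    @classmethod
    def from_array(cls, arr) -> "ConfusionMatrix3":
        arr = np.asarray(arr, dtype=int)
        if arr.shape != (3, 4):
            raise DataError(f"expected a 3x4 matrix, got shape {arr.shape}")
        return cls(*arr.ravel().tolist())

    @property
    def total(self) -> int:
        return int(self.as_array().sum())

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3.from_array(self.as_array() + other.as_array())


@dataclass(frozen=True)
class RecallSet3:
    """Per-class and overall recall rates; None where the actual-class row
    was empty."""

    rr_most: Optional[float]
    rr_less: Optional[float]
    rr_no: Optional[float]
    rr_overall: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "rr_most": self.rr_most,
            "rr_less": self.rr_less,
            "rr_no": self.rr_no,
            "rr_overall": self.rr_overall,
        }


def confusion_3class(
    predicted: Sequence[str], actual: Sequence[str], scheme: ClassScheme | None = None
) -> ConfusionMatrix3:
    """Tally the 3x4 confusion matrix; ``unknown`` predictions land in the
    U column of their actual-class row."""
    if len(predicted) != len(actual):
        raise DataError(f"{len(predicted)} predictions vs {len(actual)} actual labels")
    row = {c: i for i, c in enumerate(_ACTUAL_ORDER)}
    col = {c: j for j, c in enumerate(_PREDICTED_ORDER)}
    arr = np.zeros((3, 4), dtype=int)
    for p, a in zip(predicted, actual):
        if a not in row:
            raise DataError(f"actual label {a!r} not a 3-class label")
        if p not in col:
            raise DataError(f"predicted label {p!r} not a 3-class or unknown label")
        arr[row[a], col[p]] += 1
    return ConfusionMatrix3.from_array(arr)


def recall_rates(cm: ConfusionMatrix3, strict_printed_form: bool = False) -> RecallSet3:
    """Per-class recall rates and the overall recall rate.

    Each per-class rate is the diagonal cell over its actual-class row total
    (unknown column included).  ``strict_printed_form`` swaps the no-DILI
    denominator's NU cell for MU — an inconsistent variant kept only for
    auditing against older reports; the row-consistent form is the default.
    """
    m_row = cm.mm + cm.ml + cm.mn + cm.mu
    l_row = cm.lm + cm.ll + cm.ln + cm.lu
    n_row = cm.nm + cm.nl + cm.nn + (cm.mu if strict_printed_form else cm.nu)
    rr_m = cm.mm / m_row if m_row > 0 else None
    rr_l = cm.ll / l_row if l_row > 0 else None
    rr_n = cm.nn / n_row if n_row > 0 else None
    rr_o = (cm.mm + cm.ll + cm.nn) / cm.total if cm.total > 0 else None
    return RecallSet3(rr_m, rr_l, rr_n, rr_o)
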