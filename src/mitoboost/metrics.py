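"""Confusion-matrix construction and the six reported per-class metrics.

Per class c (with precision P and recall R computed treating c as positive):

    accuracy_bal_c = R_c        (the Average row is then the balanced accuracy)
    F_c = 2PR / (P + R)         (harmonic mean)
    G_c = sqrt(P * R)           (geometric mean)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is invariant to which class is called positive, so both class rows share
it.  All values are percentages.  Rows are kept at full precision internally;
the macro Average row is the unweighted mean of the two *unrounded* class
rows, and half-even rounding to two decimals is applied only for display —
rounding first and averaging after can differ in the second decimal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd


def round2(x: float) -> float:
    """Half-even rounding to 2 decimals on the decimal representation."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 counts with 'mitosis' as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionSummary":
        """The same tallies viewed with the negative class as positive."""
        return ConfusionSummary(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


@dataclass(frozen=True)
class MetricsRow:
    """Percentages at full precision; use .rounded() or the table for display."""

    accuracy_bal: float
    precision: float
    recall: float
    fscore: float
    mcc: float
    gmeasure: float

    def rounded(self) -> "MetricsRow":
        return MetricsRow(**{f.name: round2(getattr(self, f.name)) for f in fields(self)})

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, f.name) for f in fields(self))


def confusion_from_labels(y_true, y_pred) -> ConfusionSummary:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if not (set(np.unique(y_true)) | set(np.unique(y_pred))) <= {0, 1}:
        raise ValueError("labels must be binary {0,1}")
    return ConfusionSummary(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def mcc(cm: ConfusionSummary) -> float:
    """Matthews correlation on the [-1, 1] scale."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        warnings.warn("MCC undefined (degenerate margin); reporting 0", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / den


def per_class_metrics(cm: ConfusionSummary, positive: bool = True) -> MetricsRow:
    """The six metrics for one class row (positive = the mitosis row)."""
    view = cm if positive else cm.swapped()
    p = _safe_ratio(view.tp, view.tp + view.fp, "precision")
    r = _safe_ratio(view.tp, view.tp + view.fn, "recall")
    f = _safe_ratio(2 * p * r, p + r, "F-score") if (p + r) else 0.0
    g = math.sqrt(p * r)
    return MetricsRow(accuracy_bal=100 * r, precision=100 * p, recall=100 * r,
                      fscore=100 * f, mcc=100 * mcc(cm), gmeasure=100 * g)


def macro_average(row_pos: MetricsRow, row_neg: MetricsRow) -> MetricsRow:
    """Unweighted mean of the two class rows (computed before any rounding)."""
    return MetricsRow(*[(a + b) / 2 for a, b in zip(row_pos.as_tuple(), row_neg.as_tuple())])


COLUMNS = ("Accuracy_bal", "Precision", "Recall", "F-Score", "MCC", "G-Measure")


def metrics_table(cm: ConfusionSummary) -> pd.DataFrame:
    """Mitosis / Nonmitosis / Average rows, rounded to 2 decimals."""
    pos = per_class_metrics(cm, positive=True)
    neg = per_class_metrics(cm, positive=False)
    avg = macro_average(pos, neg)
    data = [row.rounded().as_tuple() for row in (pos, neg, avg)]
    return pd.DataFrame(data, columns=list(COLUMNS),
                        index=pd.Index(["Mitosis", "Nonmitosis", "Average"], name="Class"))


def format_table(df: pd.DataFrame) -> str:
    """Pretty fixed-width text rendering of a metrics table."""
    return df.to_string(float_format=lambda v: f"{v:.2f}")
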