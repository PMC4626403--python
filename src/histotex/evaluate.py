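"""Confusion matrices, one-vs-rest validity/security metrics, ROC curves.

The confusion matrix is oriented **rows = predicted class, columns = true
class**.  For a K-class problem each class c is evaluated one-vs-rest:

    TP = counts[c, c]          FP = row_c − TP
    FN = col_c − TP            TN = total − row_c − col_c + TP

and the five metrics — sensitivity TP/(TP+FN), specificity TN/(TN+FP),
PPV TP/(TP+FP), NPV TN/(TN+FN), ACC (TP+TN)/total — are reported in percent,
rounded half-up to two decimals; macro averages are the plain mean of the
rounded per-class values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

METRIC_NAMES = ("ppv", "npv", "sensitivity", "specificity", "acc")


def _round2(v: float) -> float:
    return float(Decimal(repr(v)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_labels = np.asarray(self.class_labels)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K×K for K class labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(pred, truth, class_labels=None) -> ConfusionMatrix:
    """Count matrix with rows = predicted, columns = true."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("pred/truth length mismatch")
    if class_labels is None:
        class_labels = np.unique(np.concatenate([pred, truth]))
    class_labels = np.asarray(class_labels)
    index = {c: i for i, c in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for p, t in zip(pred, truth):
        if p not in index or t not in index:
            raise ValueError(f"label outside the declared classes: {(p, t)}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, class_labels)


@dataclass
class ClassMetrics:
    per_class: pd.DataFrame  # rows = class labels, columns = METRIC_NAMES (%)
    macro: dict[str, float]
    flags: dict  # class → metrics whose denominator was empty

    def __getitem__(self, metric: str) -> pd.Series:
        return self.per_class[metric]


def ovr_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest metrics per class plus macro averages, in percent.

    An empty denominator (e.g. no true positives or negatives at all) is
    reported as 100 when vacuously satisfied and flagged, never silent NaN.
    """
    counts = cm.counts
    total = cm.total
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    records = {}
    flags: dict = {}
    for i, cls in enumerate(cm.class_labels):
        tp = int(counts[i, i])
        fp = int(rows[i] - tp)
        fn = int(cols[i] - tp)
        tn = int(total - rows[i] - cols[i] + tp)
        vals = {}
        for name, num, den in (("ppv", tp, tp + fp), ("npv", tn, tn + fn),
                               ("sensitivity", tp, tp + fn),
                               ("specificity", tn, tn + fp),
                               ("acc", tp + tn, total)):
            if den == 0:
                vals[name] = 100.0
                flags.setdefault(cls, []).append(name)
            else:
                vals[name] = _round2(100.0 * num / den)
        records[cls] = vals
    frame = pd.DataFrame.from_dict(records, orient="index")[list(METRIC_NAMES)]
    # exact decimal mean of the rounded cells (float means misround .005 cases)
    macro = {}
    for m in METRIC_NAMES:
        mean = sum(Decimal(repr(v)) for v in frame[m]) / len(frame)
        macro[m] = float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return ClassMetrics(frame, macro, flags)


@dataclass
class ROCCurve:
    fpr: np.ndarray  # 1 − specificity
    tpr: np.ndarray  # sensitivity
    thresholds: np.ndarray
    auc: float
    youden_index: int

    @property
    def youden_point(self) -> tuple[float, float]:
        return float(self.fpr[self.youden_index]), float(self.tpr[self.youden_index])


def roc(scores, truth) -> ROCCurve:
    """Threshold sweep over the positive-class scores; trapezoidal AUC.

    ``truth`` is binary (anything truthy = positive).  The Youden point
    maximizes sensitivity + specificity − 1.
    """
    truth = np.asarray(truth).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thr = _roc_curve(truth, scores)
    area = float(_auc(fpr, tpr))
    youden = int(np.argmax(tpr - fpr))
    return ROCCurve(fpr, tpr, thr, area, youden)


def ovr_roc_curves(result) -> dict:
    """One ROC per class from a CVResult, using its per-class scores."""
    curves = {}
    for t, cls in enumerate(result.classes):
        curves[cls] = roc(result.scores[:, t], result.truth == cls)
    return curves
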