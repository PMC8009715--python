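"""Multiclass confusion-matrix bookkeeping and the derived metric set.

For an L-class problem the confusion matrix has rows = actual class and
columns = predicted class.  One-vs-rest counts for class c are

    TP = counts[c, c]          FP = column sum - TP
    FN = row sum - TP          TN = total - TP - FP - FN

from which sensitivity (recall), specificity, PPV (precision), NPV,
accuracy, F1 and the misclassification rate follow.  Pooled summaries are
the micro F1 (F1 of the summed TP/FP/FN, which for single-label multiclass
data equals the overall accuracy), the macro F1 (unweighted mean of
per-class F1) and the support-weighted F1.  Any metric whose denominator is
zero is reported as 0 with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("mammotex")


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # rows = actual, columns = predicted
    class_labels: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "class_labels", np.asarray(self.class_labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest TP/TN/FP/FN for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Count matrix counts[i, j] = #(actual = labels[i], predicted = labels[j])."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = np.asarray(labels)
    pos = {l: i for i, l in enumerate(labels.tolist())}
    unknown = set(y_true.tolist()) | set(y_pred.tolist())
    unknown -= set(labels.tolist())
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in the declared label set")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(counts, labels)


def per_class_counts(cm: ConfusionMatrix, label) -> ClassCounts:
    i = int(np.flatnonzero(cm.class_labels == label)[0])
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return ClassCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s denominator is 0; reporting 0", name)
        return 0.0
    return num / den


def sensitivity(c: ClassCounts) -> float:
    """Recall TP/(TP+FN)."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ClassCounts) -> float:
    """TN/(TN+FP)."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def ppv(c: ClassCounts) -> float:
    """Precision TP/(TP+FP)."""
    return _ratio(c.tp, c.tp + c.fp, "ppv")


def npv(c: ClassCounts) -> float:
    """TN/(TN+FN)."""
    return _ratio(c.tn, c.tn + c.fn, "npv")


def accuracy(c: ClassCounts) -> float:
    """(TP+TN)/(TP+FP+TN+FN)."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def misclassification_rate(c: ClassCounts) -> float:
    """(FP+FN)/(TP+FP+TN+FN)."""
    return _ratio(c.fp + c.fn, c.total, "misclassification rate")


def f1(p: float, r: float) -> float:
    """Harmonic mean 2pr/(p+r), 0 when p + r = 0."""
    if p + r == 0:
        logger.warning("F1 with p + r = 0; reporting 0")
        return 0.0
    return 2 * p * r / (p + r)


def class_f1(c: ClassCounts) -> float:
    return f1(ppv(c), sensitivity(c))


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1."""
    return float(
        np.mean([class_f1(per_class_counts(cm, l)) for l in cm.class_labels])
    )


def micro_f1(cm: ConfusionMatrix) -> float:
    """F1 of the pooled TP/FP/FN across classes."""
    counts = [per_class_counts(cm, l) for l in cm.class_labels]
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    p = _ratio(tp, tp + fp, "micro precision")
    r = _ratio(tp, tp + fn, "micro recall")
    return f1(p, r)


def weighted_f1(cm: ConfusionMatrix) -> float:
    """Support-weighted mean of per-class F1 (support = actual row sums)."""
    support = cm.counts.sum(axis=1)
    if support.sum() == 0:
        return 0.0
    f1s = [class_f1(per_class_counts(cm, l)) for l in cm.class_labels]
    return float(np.dot(support, f1s) / support.sum())


def per_class_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """One row per class: raw counts plus percentage metrics (1 decimal)."""
    rows = []
    for label in cm.class_labels:
        c = per_class_counts(cm, label)
        rows.append(
            {
                "class": label,
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
                "recall_pct": round(100 * sensitivity(c), 1),
                "precision_pct": round(100 * ppv(c), 1),
                "f1_pct": round(100 * class_f1(c), 1),
                "misclassification_pct": round(100 * misclassification_rate(c), 1),
                "accuracy_pct": round(100 * accuracy(c), 1),
            }
        )
    return pd.DataFrame(rows)


def pooled_report(cm: ConfusionMatrix) -> dict[str, float]:
    """Overall summary: micro/macro/weighted F1, misclassification, and
    micro recall/precision/accuracy plus macro specificity, in percent."""
    counts = [per_class_counts(cm, l) for l in cm.class_labels]
    overall_acc = float(_ratio(np.trace(cm.counts), cm.total, "overall accuracy"))
    return {
        "micro_f1_pct": round(100 * micro_f1(cm), 2),
        "macro_f1_pct": round(100 * macro_f1(cm), 2),
        "weighted_f1_pct": round(100 * weighted_f1(cm), 2),
        "misclassification_rate_pct": round(100 * (1 - overall_acc), 2),
        "recall_pct": round(100 * overall_acc, 2),
        "specificity_pct": round(100 * float(np.mean([specificity(c) for c in counts])), 2),
        "precision_pct": round(100 * overall_acc, 2),
        "accuracy_pct": round(100 * overall_acc, 2),
    }
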