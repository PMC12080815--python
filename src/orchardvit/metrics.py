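"""Confusion-matrix evaluation: accuracy, per-class precision/recall/F1.

Multi-class TP/FP/FN/TN are computed one-vs-rest per class from the
confusion matrix (rows = true class, columns = predicted), giving

    accuracy  = (TP + TN) / (TP + FP + FN + TN)   [= trace / total overall]
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 P R / (P + R)

Macro averages are unweighted class means; weighted averages use class
supports.  Zero denominators yield 0 with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "ClassReport", "confusion", "report"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (m, m) ints; rows true, cols predicted
    labels: list | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.labels is None:
            self.labels = list(range(self.counts.shape[0]))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``k``; the four always sum to total."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass
class ClassReport:
    accuracy: float
    per_class: dict
    macro_avg: dict
    weighted_avg: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"accuracy": self.accuracy, "per_class": self.per_class,
             "macro_avg": self.macro_avg, "weighted_avg": self.weighted_avg},
            **kwargs,
        )


def confusion(y_true, y_pred, m: int | None = None, labels=None) -> ConfusionMatrix:
    """Count matrix: ``counts[i, j] = #{k : true=i, pred=j}``."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D index arrays")
    if m is None:
        m = int(max(y_true.max(initial=-1), y_pred.max(initial=-1))) + 1
    if np.any(y_true < 0) or np.any(y_true >= m) or np.any(y_pred < 0) or np.any(y_pred >= m):
        raise ValueError(f"class indices must lie in [0, {m})")
    counts = np.zeros((m, m), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, labels=list(labels) if labels is not None else None)


def _safe_div(num: float, den: float, what: str, label) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {label!r} (zero denominator); returning 0")
        return 0.0
    return num / den


def report(cm: ConfusionMatrix) -> ClassReport:
    """Per-class and averaged metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    m = cm.counts.shape[0]
    per_class: dict = {}
    supports = cm.counts.sum(axis=1)
    precisions, recalls, f1s = [], [], []
    for k in range(m):
        label = cm.labels[k]
        tp, fp, fn, tn = cm.one_vs_rest(k)
        p = _safe_div(tp, tp + fp, "precision", label)
        r = _safe_div(tp, tp + fn, "recall", label)
        f1 = _safe_div(2.0 * p * r, p + r, "f1", label)
        per_class[str(label)] = {
            "precision": p, "recall": r, "f1": f1, "support": int(supports[k]),
        }
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1)
    accuracy = float(np.trace(cm.counts)) / cm.total
    w = supports / cm.total
    macro = {"precision": float(np.mean(precisions)), "recall": float(np.mean(recalls)),
             "f1": float(np.mean(f1s))}
    weighted = {"precision": float(np.dot(w, precisions)), "recall": float(np.dot(w, recalls)),
                "f1": float(np.dot(w, f1s))}
    return ClassReport(accuracy=accuracy, per_class=per_class,
                       macro_avg=macro, weighted_avg=weighted)
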