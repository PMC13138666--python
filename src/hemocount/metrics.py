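"""Classification and counting evaluation metrics.

Per-class precision, recall and F1, overall accuracy, and macro / weighted
(support-weighted) averages for the two-class ROI / Non-ROI problem, plus
the counting accuracy used to compare automated against manual counts:

    counting accuracy [%] = measured count / actual count x 100
    counting error   [%] = |100 - accuracy|

Zero denominators (e.g. precision of a never-predicted class) yield 0 with a
warning.  Report formatting rounds to two decimals; raw values are retained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CLASS_NAMES = {0: "NON-ROI", 1: "ROI"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion matrix; ``matrix[i, j]`` counts true class i predicted j."""

    matrix: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (2, 2) or (m < 0).any():
            raise ValueError("confusion matrix must be 2x2 with counts >= 0")

    @classmethod
    def from_counts(cls, correct_0: int, miss_0: int,
                    correct_1: int, miss_1: int) -> "ConfusionMatrix":
        """Build from per-class correct/misclassified counts."""
        return cls(((correct_0, miss_0), (miss_1, correct_1)))

    @property
    def total(self) -> int:
        return int(np.sum(self.matrix))

    def support(self, cls_idx: int) -> int:
        return int(np.sum(self.matrix[cls_idx]))

    def tp(self, cls_idx: int) -> int:
        return int(self.matrix[cls_idx][cls_idx])

    def fn(self, cls_idx: int) -> int:
        return self.support(cls_idx) - self.tp(cls_idx)

    def fp(self, cls_idx: int) -> int:
        other = 1 - cls_idx
        return int(self.matrix[other][cls_idx])

    def tn(self, cls_idx: int) -> int:
        return self.total - self.tp(cls_idx) - self.fn(cls_idx) - self.fp(cls_idx)


def confusion(labels, predictions) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel 0/1 label/prediction sequences."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    if not (set(np.unique(labels)) | set(np.unique(predictions))) <= {0, 1}:
        raise ValueError("labels must be 0 (Non-ROI) or 1 (ROI)")
    m = np.zeros((2, 2), dtype=int)
    for t, p in zip(labels.ravel(), predictions.ravel()):
        m[int(t), int(p)] += 1
    return ConfusionMatrix(tuple(map(tuple, m.tolist())))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, returning 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix) -> dict[int, dict[str, float]]:
    """Per-class precision, recall and F1 (one-vs-rest)."""
    out: dict[int, dict[str, float]] = {}
    for i in (0, 1):
        p = _safe_div(cm.tp(i), cm.tp(i) + cm.fp(i), f"precision[{i}]")
        r = _safe_div(cm.tp(i), cm.tp(i) + cm.fn(i), f"recall[{i}]")
        f1 = _safe_div(2 * p * r, p + r, f"f1[{i}]")
        out[i] = {"precision": p, "recall": r, "f1": f1,
                  "support": cm.support(i)}
    return out


@dataclass
class MetricsReport:
    per_class: dict[int, dict[str, float]]
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]
    n_classes: int = 2

    @property
    def total_support(self) -> int:
        return int(sum(c["support"] for c in self.per_class.values()))

    def to_dict(self) -> dict:
        return {
            "per_class": {CLASS_NAMES[i]: dict(v) for i, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_avg": dict(self.macro),
            "weighted_avg": dict(self.weighted),
            "support": self.total_support,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def aggregate_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus macro and support-weighted averages of the class metrics."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = class_metrics(cm)
    accuracy = (cm.tp(0) + cm.tp(1)) / cm.total
    supports = np.array([per_class[i]["support"] for i in (0, 1)], dtype=float)
    macro, weighted = {}, {}
    for key in ("precision", "recall", "f1"):
        vals = np.array([per_class[i][key] for i in (0, 1)])
        macro[key] = float(vals.mean())
        weighted[key] = float((vals * supports).sum() / supports.sum())
    return MetricsReport(per_class=per_class, accuracy=accuracy,
                         macro=macro, weighted=weighted)


def format_table(report: MetricsReport) -> str:
    """Plain-text table in the classic classification-report layout."""
    r2 = lambda v: f"{v:.2f}".rstrip("0").rstrip(".")
    rows = [("Metric", "Precision", "Recall", "F1-score", "Support")]
    for i in (0, 1):
        c = report.per_class[i]
        rows.append((CLASS_NAMES[i], r2(c["precision"]), r2(c["recall"]),
                     r2(c["f1"]), str(int(c["support"]))))
    rows.append(("Accuracy", "-", "-", r2(report.accuracy),
                 str(report.total_support)))
    rows.append(("Macro avg", r2(report.macro["precision"]),
                 r2(report.macro["recall"]), r2(report.macro["f1"]),
                 str(report.total_support)))
    rows.append(("Weighted avg", r2(report.weighted["precision"]),
                 r2(report.weighted["recall"]), r2(report.weighted["f1"]),
                 str(report.total_support)))
    widths = [max(len(r[c]) for r in rows) for c in range(5)]
    return "\n".join("  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
                     for row in rows)


def counting_accuracy(measured: float, actual: float) -> tuple[float, float]:
    """Counting accuracy and error, both in percent.

    accuracy = measured / actual x 100; error = |100 - accuracy|.  Undefined
    for ``actual == 0``.
    """
    if actual <= 0:
        raise ValueError("actual count must be > 0")
    acc = measured / actual * 100.0
    return acc, abs(100.0 - acc)
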