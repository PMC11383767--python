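"""Confusion matrices and one-vs-rest classification metrics.

For class k the K-class confusion matrix (rows true, columns predicted)
reduces to TP = cm[k, k], FP = column k minus TP, FN = row k minus TP and
TN = everything else, from which

    precision  P  = TP / (TP + FP)
    recall     R  = TP / (TP + FN)
    F1            = 2 P R / (P + R)
    specificity S = TN / (TN + FP)

Overall accuracy is trace / total.  Specificity defaults to the standard
true-negative rate TN / (TN + FP); the variant with FN in the denominator,
as some reports print it, is available via ``specificity_denominator="fn"``.
Degenerate 0/0 ratios are defined as 0 and flagged with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "overall_accuracy",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints, rows = true, columns = predicted
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (arr < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``k``."""
        cm = self.counts
        tp = int(cm[k, k])
        fp = int(cm[:, k].sum()) - tp
        fn = int(cm[k, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_csv(self, path) -> None:
        labels = self.labels or tuple(str(i) for i in range(self.num_classes))
        header = "," + ",".join(labels)
        rows = [f"{lab}," + ",".join(str(v) for v in row)
                for lab, row in zip(labels, self.counts)]
        with open(path, "w") as fh:
            fh.write(header + "\n" + "\n".join(rows) + "\n")


def confusion_matrix(y_true, y_pred, num_classes: int,
                     labels: tuple[str, ...] | None = None) -> ConfusionMatrix:
    yt = np.asarray(y_true, dtype=np.int64)
    yp = np.asarray(y_pred, dtype=np.int64)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if len(yt) and (yt.min() < 0 or yt.max() >= num_classes
                    or yp.min() < 0 or yp.max() >= num_classes):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (yt, yp), 1)
    return ConfusionMatrix(counts, labels)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator in {what}; defining it as 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix, k: int,
                      specificity_denominator: str = "fp"
                      ) -> tuple[float, float, float, float]:
    """(precision, recall, specificity, F1) for class ``k``."""
    tp, fp, fn, tn = cm.one_vs_rest(k)
    p = _safe_ratio(tp, tp + fp, "precision")
    r = _safe_ratio(tp, tp + fn, "recall")
    if specificity_denominator == "fp":
        s = _safe_ratio(tn, tn + fp, "specificity")
    elif specificity_denominator == "fn":
        s = _safe_ratio(tn, tn + fn, "specificity")
    else:
        raise ValueError("specificity_denominator must be 'fp' or 'fn'")
    f1 = _safe_ratio(2.0 * p * r, p + r, "F1")
    return p, r, s, f1


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


@dataclass(frozen=True)
class MetricsReport:
    """Per-class P/R/S/F1, overall accuracy and macro averages."""

    labels: tuple[str, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    specificity: tuple[float, ...]
    f1: tuple[float, ...]
    accuracy: float
    macro: dict[str, float] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({
            "labels": list(self.labels),
            "precision": list(self.precision),
            "recall": list(self.recall),
            "specificity": list(self.specificity),
            "f1": list(self.f1),
            "accuracy": self.accuracy,
            "macro": self.macro,
        }, indent=indent)

    def format_table(self) -> str:
        width = max(len(l) for l in self.labels + ("macro",)) + 2
        lines = [f"{'class':<{width}}{'P':>8}{'R':>8}{'S':>8}{'F1':>8}"]
        for i, lab in enumerate(self.labels):
            lines.append(f"{lab:<{width}}{self.precision[i]:>8.3f}{self.recall[i]:>8.3f}"
                         f"{self.specificity[i]:>8.3f}{self.f1[i]:>8.3f}")
        m = self.macro
        lines.append(f"{'macro':<{width}}{m['precision']:>8.3f}{m['recall']:>8.3f}"
                     f"{m['specificity']:>8.3f}{m['f1']:>8.3f}")
        lines.append(f"overall accuracy: {self.accuracy:.3f}")
        return "\n".join(lines)


def plot_confusion_matrix(cm: ConfusionMatrix, path) -> None:
    """Save the count matrix as an annotated heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    labels = cm.labels or tuple(str(i) for i in range(cm.num_classes))
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(cm.num_classes), labels, rotation=45, ha="right")
    ax.set_yticks(range(cm.num_classes), labels)
    ax.set_xlabel("predicted"), ax.set_ylabel("true")
    for i in range(cm.num_classes):
        for j in range(cm.num_classes):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="white" if cm.counts[i, j] > cm.counts.max() / 2 else "black")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def metrics_report(cm: ConfusionMatrix,
                   specificity_denominator: str = "fp") -> MetricsReport:
    labels = cm.labels or tuple(str(i) for i in range(cm.num_classes))
    per = [per_class_metrics(cm, k, specificity_denominator)
           for k in range(cm.num_classes)]
    p, r, s, f1 = (tuple(row[i] for row in per) for i in range(4))
    macro = {"precision": float(np.mean(p)), "recall": float(np.mean(r)),
             "specificity": float(np.mean(s)), "f1": float(np.mean(f1))}
    return MetricsReport(labels=tuple(labels), precision=p, recall=r,
                         specificity=s, f1=f1,
                         accuracy=overall_accuracy(cm), macro=macro)
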