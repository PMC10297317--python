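"""Binary classification metrics: confusion counts, support-weighted
precision/recall/specificity/F1, overall accuracy, ROC curve and AUC.

Per-class one-vs-rest metrics are combined with support weights
``sum_c (n_c / N) * metric_c``; under this weighting the weighted recall is
algebraically identical to the overall accuracy (each class's recall is its
number of correct predictions over its support).  Accuracy is the standard
(TP + TN) / N and the ROC's false-positive rate the standard FP / (FP + TN),
i.e. 1 - specificity.  AUC is the trapezoid area under the threshold-swept
curve, which for distinct scores equals the Mann-Whitney U statistic over
(n+ * n-).  Confidence intervals on proportions use the normal
approximation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["ConfusionCounts", "ClassificationReport", "confusion",
           "weighted_metrics", "roc_auc", "classification_report",
           "proportion_confidence_interval"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def support(self) -> int:
        """Number of true instances of the reference class."""
        return self.TP + self.FN


def confusion(labels, predictions, positive_class) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    pos_l = labels == positive_class
    pos_p = predictions == positive_class
    return ConfusionCounts(TP=int((pos_l & pos_p).sum()),
                           FP=int((~pos_l & pos_p).sum()),
                           TN=int((~pos_l & ~pos_p).sum()),
                           FN=int((pos_l & ~pos_p).sum()))


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {name}; defining it as 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def _per_class(c: ConfusionCounts) -> dict[str, float]:
    precision = _safe_ratio(c.TP, c.TP + c.FP, "precision")
    recall = _safe_ratio(c.TP, c.TP + c.FN, "recall")
    specificity = _safe_ratio(c.TN, c.FP + c.TN, "specificity")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "f1")
    return dict(precision=precision, recall=recall, specificity=specificity,
                f1=f1)


@dataclass
class ClassificationReport:
    counts: dict  # class -> ConfusionCounts
    overall_accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    weighted_specificity: float
    roc_points: list = field(default_factory=list)
    auc: float = float("nan")

    def to_json(self, path) -> None:
        payload = {
            "counts": {str(k): asdict(v) for k, v in self.counts.items()},
            "overall_accuracy": self.overall_accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "weighted_specificity": self.weighted_specificity,
            "roc_points": [list(p) for p in self.roc_points],
            "auc": None if np.isnan(self.auc) else self.auc,
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "overall_accuracy": self.overall_accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "weighted_specificity": self.weighted_specificity,
            "auc": self.auc,
        }])


def weighted_metrics(per_class_counts: dict, supports: dict | None = None
                     ) -> ClassificationReport:
    """Support-weighted metrics from per-class one-vs-rest confusion counts."""
    if supports is None:
        supports = {c: counts.support for c, counts in per_class_counts.items()}
    if any(s <= 0 for s in supports.values()):
        raise ValueError("supports must be positive")
    N = sum(supports.values())
    agg = {k: 0.0 for k in ("precision", "recall", "specificity", "f1")}
    correct = 0
    n_total = None
    for cls, counts in per_class_counts.items():
        w = supports[cls] / N
        for k, v in _per_class(counts).items():
            agg[k] += w * v
        correct += counts.TP
        n_total = counts.n_total
    accuracy = correct / n_total
    return ClassificationReport(counts=dict(per_class_counts),
                                overall_accuracy=accuracy,
                                weighted_precision=agg["precision"],
                                weighted_recall=agg["recall"],
                                weighted_f1=agg["f1"],
                                weighted_specificity=agg["specificity"])


def roc_auc(scores, labels, positive_class=1) -> tuple[list, float]:
    """ROC points from a threshold sweep over the unique scores, plus the
    trapezoid AUC.  The curve runs monotonically from (0, 0) to (1, 1)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC undefined: need both classes present")
    order = np.argsort(-scores, kind="stable")
    pos_sorted = pos[order]
    score_sorted = scores[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # keep the last point of each tied-score block
    distinct = np.r_[score_sorted[1:] != score_sorted[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos, 1.0]
    fpr = np.r_[0.0, fps[distinct] / n_neg, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def proportion_confidence_interval(p: float, n: int, level: float = 0.90
                                   ) -> tuple[float, float]:
    """Normal-approximation CI for a proportion (90 % by default)."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def render_confusion_png(counts: ConfusionCounts, path,
                         class_names=("Healthy", "ICU")) -> None:
    """2x2 confusion-matrix heatmap (rows: true, columns: predicted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = np.array([[counts.TN, counts.FP], [counts.FN, counts.TP]])
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(matrix, cmap="Blues")
    for (i, j), v in np.ndenumerate(matrix):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], class_names)
    ax.set_yticks([0, 1], class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def classification_report(labels, predictions, scores=None,
                          positive_class=None) -> ClassificationReport:
    """Assemble the full report from label/prediction (and optional score)
    sequences.  Scores are positive-class probabilities for the ROC."""
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    per_class = {c: confusion(labels, predictions, c) for c in classes}
    report = weighted_metrics(per_class)
    if scores is not None:
        if positive_class is None:
            positive_class = classes[-1]
        report.roc_points, report.auc = roc_auc(scores, labels, positive_class)
    return report
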