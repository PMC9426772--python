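"""Threshold metrics, ROC/PR areas, and the repeated-split report.

Threshold metrics follow the standard confusion-matrix formulas:

    Acc  = (TP+TN) / (TP+TN+FP+FN)
    Sen  = TP / (TP+FN)          Spec = TN / (TN+FP)
    Prec = TP / (TP+FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Undefined ratios (zero denominators) are reported as 0 with a degenerate
flag so aggregation across repeats stays total. AUC is the trapezoidal area
under the ROC curve (equal to the Mann-Whitney rank statistic with ties
counted half); AUPR is the step integral of the precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "roc_auc",
    "pr_auc",
    "roc_curve_points",
    "pr_curve_points",
]

METRIC_NAMES = ("Acc", "Sen", "Spec", "Prec", "MCC", "AUC", "AUPR")


class UndefinedMetricError(ValueError):
    """Both classes are required for a ranking metric."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(np.int64)


def confusion_counts(
    labels, scores, threshold: float = 0.5
) -> ConfusionCounts:
    """Tally the confusion matrix with the 'score >= threshold' rule."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Threshold metrics from confusion counts; degenerate ratios become 0."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero samples")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    degenerate = False
    acc = (tp + tn) / counts.total
    sen, d1 = _safe_div(tp, tp + fn)
    spec, d2 = _safe_div(tn, tn + fp)
    prec, d3 = _safe_div(tp, tp + fp)
    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc, d4 = _safe_div(tp * tn - fp * fn, mcc_den)
    degenerate = d1 or d2 or d3 or d4
    return {
        "Acc": acc,
        "Sen": sen,
        "Spec": spec,
        "Prec": prec,
        "MCC": mcc,
        "degenerate": degenerate,
    }


def _check_two_class(labels) -> np.ndarray:
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            "AUC/AUPR require both classes in the labels"
        )
    return labels


def roc_auc(labels, scores) -> float:
    """Trapezoidal area under the ROC curve."""
    labels = _check_two_class(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(auc(fpr, tpr))


def pr_auc(labels, scores) -> float:
    """Step-integrated area under the precision-recall curve."""
    labels = _check_two_class(labels)
    return float(average_precision_score(labels, scores))


def roc_curve_points(labels, scores) -> pd.DataFrame:
    labels = _check_two_class(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def pr_curve_points(labels, scores) -> pd.DataFrame:
    labels = _check_two_class(labels)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return pd.DataFrame({"recall": rec[::-1], "precision": prec[::-1]})


@dataclass
class MetricsReport:
    """Per-repeat metric table with mean and standard deviation rows."""

    per_repeat: pd.DataFrame
    extra: dict = field(default_factory=dict)

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat[list(METRIC_NAMES)].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_repeat[list(METRIC_NAMES)].std(ddof=1)

    def summary(self) -> pd.DataFrame:
        """Repeat rows plus an 'Average' row formatted as mean +/- std."""
        body = self.per_repeat[list(METRIC_NAMES)].copy()
        body.index = [f"repeat {i}" for i in range(len(body))]
        avg = {
            name: f"{self.mean[name]:.4f}±{self.std[name]:.4f}"
            for name in METRIC_NAMES
        }
        out = body.round(4).astype(str)
        out.loc["Average"] = pd.Series(avg)
        return out

    def to_dict(self) -> dict:
        return {
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "mean": self.mean.to_dict(),
            "std": self.std.to_dict(),
            **self.extra,
        }
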