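"""Evaluation metrics for variant scores.

Seven metrics per (scores, labels) pair: ROC AUC, area under the
precision-recall curve (average precision), accuracy, precision, recall,
F1 and specificity, the last five at a stated decision threshold with the
rule ``score > threshold``. Zero-denominator cells are reported as 0 and
flagged rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .cnn import TrainedModel, score as model_score

__all__ = [
    "MetricsReport", "roc_auc", "pr_auc", "classification_metrics",
    "compare_models",
]


def _check(scores, labels, need_both=True):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if s.shape != y.shape or s.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if need_both and (n_pos == 0 or n_neg == 0):
        raise ValueError("both classes must be present")
    return s, y, n_pos, n_neg


@dataclass
class MetricsReport:
    """The seven evaluation metrics for one (scores, labels) pair."""

    auc: float
    auprc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    threshold_used: float
    n_pos: int
    n_neg: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "auprc": self.auprc, "accuracy": self.accuracy,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "specificity": self.specificity,
            "threshold_used": self.threshold_used,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "flags": ";".join(self.flags),
        }


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney statistic P(score_pos > score_neg) + half the
    tie probability over all positive-negative pairs.
    """
    s, y, _, _ = _check(scores, labels)
    return float(roc_auc_score(y, s))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve by the step rule (average
    precision), avoiding optimistic trapezoidal interpolation."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if s.shape != y.shape or s.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if int((y == 1).sum()) == 0:
        raise ValueError("at least one positive required")
    return float(average_precision_score(y, s))


def classification_metrics(scores, labels, threshold: float) -> MetricsReport:
    """All seven metrics at the decision rule ``score > threshold``."""
    s, y, n_pos, n_neg = _check(scores, labels)
    pred = s > threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(f"{name} denominator zero")
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    accuracy = (tp + tn) / len(y)
    return MetricsReport(
        auc=roc_auc(s, y),
        auprc=pr_auc(s, y),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        threshold_used=float(threshold),
        n_pos=n_pos,
        n_neg=n_neg,
        flags=flags,
    )


def compare_models(
    models: dict[str, TrainedModel],
    test_matrix,
    test_labels,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """One metrics row per named model on the identical test set.

    Models whose input length does not match the matrix get an ``error``
    entry instead of metrics.
    """
    rows = []
    for name, model in models.items():
        try:
            s = model_score(model, test_matrix)
            rep = classification_metrics(s, test_labels, threshold)
            rows.append({"model": name, **rep.to_dict(), "error": ""})
        except ValueError as exc:
            rows.append({"model": name, "error": str(exc)})
    return pd.DataFrame(rows)
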