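"""Classifier performance metrics: PPV, AUC, recall, ROC points."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["Metrics", "compute_metrics"]


@dataclass
class Metrics:
    ppv: float | None  # undefined (None) when nothing is predicted sensitive
    auc: float | None  # undefined when only one class present
    recall: float | None
    n_predicted_sensitive: int
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray


def compute_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> Metrics:
    """PPV / AUC / recall of probability scores against binary labels.

    PPV = true sensitives among predicted sensitives / predicted sensitives
    (equal to class prevalence under predict-all); AUC is the trapezoidal
    area under the probability-ranked ROC with tied scores handled by
    midrank.  A call is sensitive when probability exceeds the threshold.
    """
    prob = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = prob > threshold
    n_pred = int(pred.sum())
    tp = int((pred & (y == 1)).sum())
    ppv = tp / n_pred if n_pred > 0 else None
    recall = tp / int((y == 1).sum()) if (y == 1).any() else None
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, prob))
        fpr, tpr, thr = roc_curve(y, prob)
    else:
        auc = None
        fpr = tpr = thr = np.array([])
    return Metrics(
        ppv=ppv,
        auc=auc,
        recall=recall,
        n_predicted_sensitive=n_pred,
        roc_fpr=fpr,
        roc_tpr=tpr,
        roc_thresholds=thr,
    )
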