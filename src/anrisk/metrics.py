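"""Classification performance metrics.

Thin, validated wrappers around scikit-learn's ranking metrics: ROC-AUC
(probability that a random positive outscores a random negative, ties
counted one half) and PR-AUC computed as average precision, i.e. the
step-function summation over recall increments without linear interpolation
between PR points.  PR-AUC is the optimization metric of the pipeline
because it is sensitive to class imbalance; ROC-AUC allows comparison across
tasks with different class ratios.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import UndefinedMetricError

__all__ = ["roc_auc", "pr_auc"]


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D vectors of equal length")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1, True, False}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    return scores, labels.astype(int)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; requires both classes present."""
    scores, labels = _check(scores, labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("ROC-AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Precision-recall AUC as average precision; requires positives present."""
    scores, labels = _check(scores, labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("PR-AUC undefined: no positive labels")
    return float(average_precision_score(labels, scores))
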