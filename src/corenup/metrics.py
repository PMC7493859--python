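"""Binary classification metrics for nucleosome/linker evaluation.

The nucleosome class is the positive class.  Scores are class-1
probabilities; the decision threshold defaults to 0.5 and a score
exactly at the threshold is classified positive.

Metrics from the confusion table::

    ACC  = (TP + TN) / (TP + FP + TN + FN)
    SENS = TP / (TP + FN)
    SPEC = TN / (TN + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP))

ROC/AUC: the ROC curve is swept over all distinct score thresholds and
the area computed by trapezoidal integration; this equals the pairwise
concordance probability P(score+ > score-) + 0.5 * P(tie).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class ConfusionCounts:
    """The 2x2 confusion table (positive class = nucleosome)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return scores, labels.astype(int)


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion table at ``threshold`` (score >= threshold -> positive)."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN); 0 when no positives were evaluated."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def specificity(c: ConfusionCounts, printed_variant: bool = False) -> float:
    """True-negative rate TN/(TN+FP).

    ``printed_variant=True`` computes TN/(TN+FN) instead -- a
    compatibility option for published tables that use that nonstandard
    form.
    """
    denom = (c.tn + c.fn) if printed_variant else (c.tn + c.fp)
    return c.tn / denom if denom else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (with a warning) when any
    marginal of the confusion table is empty."""
    denom2 = ((c.tn + c.fn) * (c.tn + c.fp) * (c.tp + c.fn) * (c.tp + c.fp))
    if denom2 == 0:
        warnings.warn("MCC denominator is zero (degenerate confusion "
                      "table); returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom2)


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """ROC AUC by trapezoidal integration.

    Returns ``(auc, curve)`` where ``curve`` is the list of (FPR, TPR)
    points swept over all distinct thresholds.  Raises on single-class
    labels, for which the AUC is undefined.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("AUC is undefined for single-class labels")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """All five headline metrics in one dict: ACC, SENS, SPEC, MCC, AUC."""
    c = confusion(scores, labels, threshold)
    return {
        "ACC": accuracy(c),
        "SENS": sensitivity(c),
        "SPEC": specificity(c),
        "MCC": mcc(c),
        "AUC": roc_auc(scores, labels)[0],
    }
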