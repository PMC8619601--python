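"""Confusion-matrix metrics for the binary normal/abnormal task.

Convention: abnormal is the positive class (a true positive is a correctly
detected abnormal slice). "TP rate" is sensitivity ``tp/(tp+fn)`` and
"FP rate" is ``fp/(fp+tn) = 1 - specificity``.

Counts may be real-valued: reconstructing a confusion matrix from printed
rates (``tp = tp_rate * n_pos`` etc.) generally yields fractional cells, and
rounding them loses agreement with published 4-decimal kappa values, so the
fractions are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN cell counts (real-valued allowed, all nonnegative)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        """Tally counts from 0/1 label arrays (1 = abnormal = positive)."""
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("label arrays must have equal shape")
        return cls(
            tp=float(np.sum((y_true == 1) & (y_pred == 1))),
            fp=float(np.sum((y_true == 0) & (y_pred == 1))),
            tn=float(np.sum((y_true == 0) & (y_pred == 0))),
            fn=float(np.sum((y_true == 1) & (y_pred == 0))),
        )


def precision(c: ConfusionCounts) -> float:
    """tp / (tp + fp) — fraction of abnormal calls that are correct."""
    denom = c.tp + c.fp
    if denom == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """tp / (tp + fn) — fraction of abnormal slices detected (sensitivity)."""
    denom = c.tp + c.fn
    if denom == 0:
        raise UndefinedMetricError("recall undefined: no actual positives")
    return c.tp / denom


def tp_rate(c: ConfusionCounts) -> float:
    """Alias for sensitivity/recall, matching the evaluation tables."""
    return recall(c)


def fp_rate(c: ConfusionCounts) -> float:
    """fp / (fp + tn) — 1 minus specificity."""
    denom = c.fp + c.tn
    if denom == 0:
        raise UndefinedMetricError("fp_rate undefined: no actual negatives")
    return c.fp / denom


def accuracy(c: ConfusionCounts) -> float:
    """(tp + tn) / n — the observed agreement po."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on empty counts")
    return (c.tp + c.tn) / c.total


def cohen_kappa(c: ConfusionCounts) -> float:
    """Chance-corrected agreement ``(po - pe) / (1 - pe)``.

    ``po`` is the observed accuracy and ``pe`` the agreement expected from
    the row/column marginals alone (marginal-product chance agreement).
    Ranges over [-1, 1]; 1 is perfect, 0 is chance-level.
    """
    n = c.total
    if n == 0:
        raise UndefinedMetricError("kappa undefined on empty counts")
    po = (c.tp + c.tn) / n
    pred_pos = (c.tp + c.fp) / n
    pred_neg = (c.tn + c.fn) / n
    act_pos = (c.tp + c.fn) / n
    act_neg = (c.tn + c.fp) / n
    pe = pred_pos * act_pos + pred_neg * act_neg
    if pe >= 1.0:
        raise UndefinedMetricError("kappa undefined: degenerate one-cell matrix")
    return (po - pe) / (1.0 - pe)


def kappa_from_rates(
    tp_rate: float, fp_rate: float, n_pos: float, n_neg: float
) -> float:
    """Kappa implied by printed sensitivity / false-positive rate.

    Rebuilds the (real-valued) confusion matrix ``tp = tp_rate * n_pos``,
    ``fn = n_pos - tp``, ``fp = fp_rate * n_neg``, ``tn = n_neg - fp`` and
    applies :func:`cohen_kappa`. Used to check published rate tables for
    internal consistency.
    """
    if not (0.0 <= tp_rate <= 1.0 and 0.0 <= fp_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    tp = tp_rate * n_pos
    fp = fp_rate * n_neg
    return cohen_kappa(
        ConfusionCounts(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank-sum identity.

    Equals the probability that a random positive outscores a random
    negative, with ties counting half — identical to the trapezoidal area
    under the TP-rate vs FP-rate curve.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks give half-credit ties
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass(frozen=True)
class MetricReport:
    """The evaluation-table row: kappa, rates, precision/recall, AUC."""

    kappa: float
    tp_rate: float
    fp_rate: float
    auc: float
    recall: float
    precision: float
    accuracy: float

    @classmethod
    def from_scores(cls, labels, scores, threshold: float = 0.5) -> "MetricReport":
        """Score-based report: threshold at 0.5 for counts, ranks for AUC."""
        labels = np.asarray(labels)
        scores = np.asarray(scores, dtype=np.float64)
        preds = (scores >= threshold).astype(np.int64)
        c = ConfusionCounts.from_labels(labels, preds)
        return cls(
            kappa=cohen_kappa(c),
            tp_rate=tp_rate(c),
            fp_rate=fp_rate(c),
            auc=roc_auc(scores, labels),
            recall=recall(c),
            precision=precision(c) if (c.tp + c.fp) > 0 else float("nan"),
            accuracy=accuracy(c),
        )

    def to_dict(self) -> dict[str, float]:
        """Serialize with the evaluation tables' column names."""
        return {
            "Kappa Statistics": self.kappa,
            "TP Rate": self.tp_rate,
            "FP Rate": self.fp_rate,
            "ROC": self.auc,
            "Recall": self.recall,
            "Precision": self.precision,
            "Accuracy": self.accuracy,
        }
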