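"""Segmentation losses and evaluation statistics.

Per-pair definitions, with X the predicted foreground set and Y the
reference foreground set (pixel counts TP/FP/FN/TN):

* Dice         2|X∩Y| / (|X|+|Y|);  Dice loss = 1 − Dice
* IoU ("mIoU") TP / (TP+FP+FN); dataset-level value is the mean of
  per-image foreground IoU
* precision    TP / (TP+FP)
* recall       TP / (TP+FN)
* ROC/AUC      sensitivity vs 1−specificity swept over distinct
  probability thresholds; area by the trapezoid rule

Degenerate denominators follow fixed conventions (warned, never raised):
both masks empty → Dice loss 0 and IoU 1 (perfect agreement); no predicted
/ no reference positives → precision / recall 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InputError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "dice_coefficient",
    "dice_loss",
    "soft_dice_loss",
    "miou",
    "precision_recall",
    "pixel_accuracy",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Bundle of evaluation statistics for one run (all in [0, 1])."""

    dice: float
    dice_loss: float
    miou: float
    precision: float
    recall: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "dice_loss": self.dice_loss,
            "miou": self.miou,
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
        }


def _check_binary_pair(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise InputError(f"mask shape mismatch: {pred.shape} vs {ref.shape}")
    for name, m in (("pred", pred), ("ref", ref)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise InputError(f"{name} mask is not binary (values {vals[:5]}...)")
    return pred.astype(bool), ref.astype(bool)


def confusion_counts(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of the binary confusion table."""
    p, r = _check_binary_pair(pred, ref)
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = int(np.count_nonzero(~p & ~r))
    return ConfusionCounts(tp, fp, fn, tn)


def dice_coefficient(pred: np.ndarray, ref: np.ndarray) -> float:
    p, r = _check_binary_pair(pred, ref)
    inter = int(np.count_nonzero(p & r))
    total = int(np.count_nonzero(p)) + int(np.count_nonzero(r))
    if total == 0:
        warnings.warn("both masks empty; Dice defined as 1 (perfect agreement)")
        return 1.0
    return 2.0 * inter / total


def dice_loss(pred: np.ndarray, ref: np.ndarray) -> float:
    """Hard (binary) Dice loss, 1 − Dice."""
    return 1.0 - dice_coefficient(pred, ref)


def soft_dice_loss(prob: np.ndarray, ref: np.ndarray, eps: float = 1e-6) -> float:
    """Dice loss on probability maps — the training objective's value.

    Uses the same 2|X∩Y|/(|X|+|Y|) form with soft intersection Σ p·y and
    soft cardinalities Σ p, Σ y; ``eps`` guards the empty-empty case.
    """
    prob = np.asarray(prob, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if prob.shape != ref.shape:
        raise InputError(f"shape mismatch: {prob.shape} vs {ref.shape}")
    num = 2.0 * float((prob * ref).sum()) + eps
    den = float(prob.sum()) + float(ref.sum()) + eps
    return 1.0 - num / den


def miou(pred: np.ndarray, ref: np.ndarray) -> float:
    """Foreground intersection-over-union TP/(TP+FP+FN) for one mask pair."""
    c = confusion_counts(pred, ref)
    den = c.tp + c.fp + c.fn
    if den == 0:
        warnings.warn("both masks empty; IoU defined as 1 (perfect agreement)")
        return 1.0
    return c.tp / den


def precision_recall(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    c = confusion_counts(pred, ref)
    if c.tp + c.fp == 0:
        warnings.warn("no predicted positives; precision defined as 0")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("no reference positives; recall defined as 0")
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    return precision, recall


def pixel_accuracy(pred: np.ndarray, ref: np.ndarray) -> float:
    """(TP+TN)/total — logged during training as scalar 'accuracy'."""
    c = confusion_counts(pred, ref)
    return (c.tp + c.tn) / c.total


def roc_auc(probs: np.ndarray, ref: np.ndarray
            ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve and area under it for a pixel-probability map.

    Returns ``((fpr, tpr), auc)`` with the full threshold sweep over
    distinct probability values and the trapezoid-rule area.
    """
    probs = np.asarray(probs, dtype=np.float64).ravel()
    ref = np.asarray(ref).ravel()
    if probs.shape != ref.shape:
        raise InputError("probability map and reference differ in size")
    if probs.min() < 0 or probs.max() > 1:
        raise InputError("probabilities must lie in [0, 1]")
    classes = np.unique(ref)
    if not np.isin(classes, (0, 1)).all() or len(classes) < 2:
        raise InputError("reference must contain both classes for ROC/AUC")
    fpr, tpr, _ = _sk_roc_curve(ref.astype(int), probs, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc
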