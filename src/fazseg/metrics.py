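"""Overlap metrics for binary segmentations and the soft dice loss.

With ground truth GT and prediction P as pixel sets:

    J = |GT & P| / |GT | P|            (Jaccard index)
    D = 2 |GT & P| / (|GT| + |P|)      (dice coefficient)

both in [0, 1], related by D = 2J / (1 + J).  Conventions for degenerate
masks: two empty masks agree perfectly (D = J = 1); one empty mask gives
D = J = 0.  The training loss is 1 - D with set cardinalities replaced by
sums over a probability map (smoothed to stay differentiable).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["jaccard", "dice", "soft_dice_loss", "summarize"]

SMOOTH = 1e-6


def _as_binary(mask, name):
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return m.astype(bool)


def _check_pair(gt, pred):
    gt = _as_binary(gt, "gt")
    pred = _as_binary(pred, "pred")
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    return gt, pred


def jaccard(gt, pred) -> float:
    """Intersection over union of two binary masks."""
    gt, pred = _check_pair(gt, pred)
    union = np.logical_or(gt, pred).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(gt, pred).sum() / union)


def dice(gt, pred) -> float:
    """Dice coefficient of two binary masks."""
    gt, pred = _check_pair(gt, pred)
    total = int(gt.sum()) + int(pred.sum())
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(gt, pred).sum() / total)


def soft_dice_loss(gt, prob, smoothing: float = SMOOTH) -> float:
    """Differentiable dice loss, 1 - soft-D, for a probability map.

    Set cardinalities are replaced by sums: soft-D =
    (2 * sum(gt * p) + s) / (sum(gt) + sum(p) + s).
    """
    gt = np.asarray(gt, dtype=np.float64)
    prob = np.asarray(prob, dtype=np.float64)
    if gt.shape != prob.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {prob.shape}")
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    inter = float((gt * prob).sum())
    denom = float(gt.sum() + prob.sum())
    return 1.0 - (2.0 * inter + smoothing) / (denom + smoothing)


def soft_dice_grad(gt, prob, smoothing: float = SMOOTH):
    """Loss value and gradient w.r.t. ``prob`` (used by the trainer)."""
    gt = np.asarray(gt, dtype=np.float32)
    prob = np.asarray(prob, dtype=np.float32)
    inter = float((gt * prob).sum())
    denom = float(gt.sum() + prob.sum())
    num = 2.0 * inter + smoothing
    den = denom + smoothing
    loss = 1.0 - num / den
    grad = -(2.0 * gt * den - num) / (den * den)
    return loss, grad.astype(np.float32)


def summarize(values):
    """Mean and sample standard deviation (n-1 denominator) of metrics."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list")
    if values.size == 1:
        warnings.warn("sample SD undefined for a single value; returning 0.0")
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1))
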