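"""Training losses: soft Dice over foreground classes plus weighted
categorical cross-entropy, with analytic gradients w.r.t. logits.

Both losses use epsilon 1e-5; the combined total is the weighted sum
``dice_weight * soft_dice + cce_weight * weighted_cce`` (exact linearity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EPS", "LossBreakdown", "softmax", "soft_dice_loss",
           "weighted_cce", "combined_loss"]

EPS = 1e-5


@dataclass(frozen=True)
class LossBreakdown:
    soft_dice: float
    weighted_cce: float
    total: float


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def _check_shapes(probabilities: np.ndarray, one_hot_truth: np.ndarray) -> None:
    if probabilities.shape != one_hot_truth.shape:
        raise ValueError(
            f"shape mismatch: {probabilities.shape} vs {one_hot_truth.shape}")


def soft_dice_loss(probabilities: np.ndarray, one_hot_truth: np.ndarray) -> float:
    """``1 - mean over foreground classes of (2*sum(p*g)+eps)/(sum p + sum g + eps)``.

    Class axis is axis 0; class 0 is background and excluded from the mean.
    """
    _check_shapes(probabilities, one_hot_truth)
    p = probabilities.reshape(probabilities.shape[0], -1)
    g = one_hot_truth.reshape(one_hot_truth.shape[0], -1)
    inter = (p[1:] * g[1:]).sum(axis=1)
    denom = p[1:].sum(axis=1) + g[1:].sum(axis=1)
    dice = (2.0 * inter + EPS) / (denom + EPS)
    return float(1.0 - dice.mean())


def _soft_dice_grad(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """dL/dp for the soft Dice loss (same shape as p, zeros for background)."""
    shape = p.shape
    pf = p.reshape(shape[0], -1)
    gf = g.reshape(shape[0], -1)
    grad = np.zeros_like(pf)
    n_fg = shape[0] - 1
    inter = (pf[1:] * gf[1:]).sum(axis=1)
    denom = pf[1:].sum(axis=1) + gf[1:].sum(axis=1) + EPS
    num = 2.0 * inter + EPS
    # d/dp_i [ num/denom ] = (2 g_i * denom - num) / denom^2
    grad[1:] = -(2.0 * gf[1:] * denom[:, None] - num[:, None]) / (denom[:, None] ** 2)
    grad[1:] /= n_fg
    return grad.reshape(shape)


def weighted_cce(probabilities: np.ndarray, one_hot_truth: np.ndarray,
                 class_weights: np.ndarray | None = None) -> float:
    """``-mean over voxels of w[true] * log(p[true] + eps)``."""
    _check_shapes(probabilities, one_hot_truth)
    n_classes = probabilities.shape[0]
    if class_weights is None:
        class_weights = np.ones(n_classes)
    class_weights = np.asarray(class_weights, dtype=float)
    if class_weights.shape != (n_classes,):
        raise ValueError("class_weights length must equal number of classes")
    if (class_weights < 0).any():
        raise ValueError("class weights must be non-negative")
    p_true = (probabilities * one_hot_truth).sum(axis=0)
    w_true = np.tensordot(class_weights, one_hot_truth, axes=(0, 0))
    return float(-(w_true * np.log(p_true + EPS)).mean())


def _weighted_cce_grad(p: np.ndarray, g: np.ndarray,
                       class_weights: np.ndarray) -> np.ndarray:
    n_vox = int(np.prod(p.shape[1:]))
    w = class_weights.reshape((-1,) + (1,) * (p.ndim - 1))
    return -(w * g) / ((p + EPS) * n_vox)


def combined_loss(logits: np.ndarray, one_hot_truth: np.ndarray,
                  class_weights: np.ndarray | None = None,
                  dice_weight: float = 1.0, cce_weight: float = 1.0,
                  with_grad: bool = True) -> tuple[LossBreakdown, np.ndarray | None]:
    """Softmax the logits, evaluate both losses, and (optionally) return the
    gradient of the weighted total w.r.t. the logits."""
    n_classes = logits.shape[0]
    if class_weights is None:
        class_weights = np.ones(n_classes)
    class_weights = np.asarray(class_weights, dtype=float)
    p = softmax(logits)
    dice = soft_dice_loss(p, one_hot_truth)
    cce = weighted_cce(p, one_hot_truth, class_weights)
    breakdown = LossBreakdown(
        soft_dice=dice, weighted_cce=cce,
        total=dice_weight * dice + cce_weight * cce)
    if not with_grad:
        return breakdown, None
    dp = (dice_weight * _soft_dice_grad(p, one_hot_truth)
          + cce_weight * _weighted_cce_grad(p, one_hot_truth, class_weights))
    # chain through softmax: dz = p * (dp - sum_c p_c dp_c)
    dz = p * (dp - (p * dp).sum(axis=0, keepdims=True))
    return breakdown, dz
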