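"""Training losses: soft Dice, pixel-wise binary cross-entropy, and their
weighted combination.

The Dice loss is a global overlap measure between the predicted
probability map and the binary target, relaxed to soft maps via the
product/sum formulation::

    intersection = sum(pred * target)
    union        = sum(pred) + sum(target) - intersection
    dice_loss    = 1 - (intersection + eps) / (union + eps)

so that identical masks score 0, disjoint masks score 1, and an empty
prediction on an empty target scores 0 (a correctly rejected negative).
The cross-entropy term is the mean negative log-likelihood per pixel and
keeps the per-pixel calibration sharp where Dice only sees the outline.
The combined objective is ``dice + beta * cate`` with ``beta`` defaulting
to 0.5.

Each loss has a companion ``*_grad`` returning the analytic gradient with
respect to the prediction, used by the training loop's backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DICE_EPS",
    "CATE_EPS",
    "DEFAULT_BETA",
    "LossValue",
    "dice_loss",
    "cate_loss",
    "total_loss",
    "dice_loss_grad",
    "cate_loss_grad",
    "total_loss_grad",
]

DICE_EPS = 1e-6
CATE_EPS = 1e-7
DEFAULT_BETA = 0.5


@dataclass(frozen=True)
class LossValue:
    value: float
    dice: float
    cate: float
    beta: float


def _check_shapes(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {target.shape}")
    return pred, target


def dice_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Soft Dice loss in [0, 1]; 0 for perfect overlap."""
    pred, target = _check_shapes(pred, target)
    inter = float((pred * target).sum())
    union = float(pred.sum() + target.sum() - inter)
    return 1.0 - (inter + DICE_EPS) / (union + DICE_EPS)


def dice_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d dice_loss / d pred (elementwise)."""
    pred, target = _check_shapes(pred, target)
    inter = (pred * target).sum()
    union = pred.sum() + target.sum() - inter
    num, den = inter + DICE_EPS, union + DICE_EPS
    # loss = 1 - num/den; d num = target; d den = 1 - target
    return -(target * den - num * (1.0 - target)) / den**2


def cate_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean negative binary log-likelihood per pixel, probabilities clipped
    to [eps, 1-eps]."""
    pred, target = _check_shapes(pred, target)
    p = np.clip(pred, CATE_EPS, 1.0 - CATE_EPS)
    return float(-(target * np.log(p) + (1.0 - target) * np.log1p(-p)).mean())


def cate_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d cate_loss / d pred; zero where the clip is active."""
    pred, target = _check_shapes(pred, target)
    p = np.clip(pred, CATE_EPS, 1.0 - CATE_EPS)
    g = (-(target / p) + (1.0 - target) / (1.0 - p)) / pred.size
    g[(pred < CATE_EPS) | (pred > 1.0 - CATE_EPS)] = 0.0
    return g


def total_loss(pred: np.ndarray, target: np.ndarray, beta: float = DEFAULT_BETA) -> LossValue:
    """Weighted combination ``dice + beta * cate`` with component report."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    d = dice_loss(pred, target)
    c = cate_loss(pred, target)
    return LossValue(value=d + beta * c, dice=d, cate=c, beta=beta)


def total_loss_grad(pred: np.ndarray, target: np.ndarray, beta: float = DEFAULT_BETA) -> np.ndarray:
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return dice_loss_grad(pred, target) + beta * cate_loss_grad(pred, target)


# ---------------------------------------------------------------------------
# batched forms used by the training loop: Dice is computed per sample and
# averaged (it is a whole-image overlap measure), cross-entropy over all
# pixels of the batch.


def batch_total_loss(pred: np.ndarray, target: np.ndarray, beta: float) -> LossValue:
    n = pred.shape[0]
    dices = [dice_loss(pred[i], target[i]) for i in range(n)]
    d = float(np.mean(dices))
    c = cate_loss(pred, target)
    return LossValue(value=d + beta * c, dice=d, cate=c, beta=beta)


def batch_total_loss_grad(pred: np.ndarray, target: np.ndarray, beta: float) -> np.ndarray:
    n = pred.shape[0]
    g = np.stack([dice_loss_grad(pred[i], target[i]) for i in range(n)]) / n
    # cate_loss over the whole batch already divides by the full pixel count
    return g + beta * cate_loss_grad(pred, target)
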