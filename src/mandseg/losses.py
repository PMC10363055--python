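"""Training objectives: Dice, Tversky and Focal Tversky losses.

All three are functions of soft confusion counts over a probability map p
and a binary ground truth g:

    TP = sum p*g,  FN = sum (1-p)*g,  FP = sum p*(1-g)

    DL  = 1 - (2 TP + s) / (2 TP + FN + FP + s)
    TL  = 1 - (TP + s) / (TP + a*FN + b*FP + s)
    FTL = TL ** gamma

with smoothing term s.  The weighting convention is: ``alpha`` multiplies
the false negatives and ``beta`` the false positives, so beta > alpha
penalizes false positives more in this parameterization; both weights are
exposed, so the opposite emphasis is obtained by swapping the values.
With alpha = beta = 0.5 the Tversky loss reduces exactly to the Dice
loss, and gamma = 1 reduces the focal variant to plain Tversky.  gamma > 1
steepens the loss surface for poorly overlapping (TI < 0.5) examples.

Defaults alpha = 0.3, beta = 0.7, gamma = 4/3.

Analytic gradients with respect to p are provided for the NumPy training
loop and are verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "LossParams",
    "soft_confusion",
    "dice_loss",
    "tversky_loss",
    "focal_tversky_loss",
    "loss_and_grad",
    "LOSS_NAMES",
]

LOSS_NAMES = ("dice", "tversky", "focal_tversky")


@dataclass(frozen=True)
class ConfusionCounts:
    """Soft confusion counts; for hard 0/1 inputs these are voxel counts."""

    tp: float
    fn: float
    fp: float

    def __post_init__(self):
        if self.tp < 0 or self.fn < 0 or self.fp < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class LossParams:
    alpha: float = 0.3   # weight on false negatives
    beta: float = 0.7    # weight on false positives
    gamma: float = 4.0 / 3.0
    smooth: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.smooth < 0:
            raise ValueError("smooth must be >= 0")


def soft_confusion(prob_volume: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Soft TP/FN/FP sums of a probability map against a binary truth."""
    p = np.asarray(prob_volume, dtype=np.float64)
    g = np.asarray(truth_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = float(np.sum(p * g))
    fn = float(np.sum((1.0 - p) * g))
    fp = float(np.sum(p * (1.0 - g)))
    return ConfusionCounts(tp, fn, fp)


def _check_defined(denom: float) -> None:
    if denom == 0.0:
        raise ZeroDivisionError(
            "undefined loss: all confusion counts zero with smooth = 0"
        )


def dice_loss(counts: ConfusionCounts, smooth: float = 0.0) -> float:
    """1 - (2 TP + s) / (2 TP + FN + FP + s)."""
    denom = 2.0 * counts.tp + counts.fn + counts.fp + smooth
    _check_defined(denom)
    return 1.0 - (2.0 * counts.tp + smooth) / denom


def tversky_loss(counts: ConfusionCounts, params: LossParams = LossParams()) -> float:
    """1 - (TP + s) / (TP + alpha*FN + beta*FP + s)."""
    denom = counts.tp + params.alpha * counts.fn + params.beta * counts.fp + params.smooth
    _check_defined(denom)
    return 1.0 - (counts.tp + params.smooth) / denom


def focal_tversky_loss(counts: ConfusionCounts, params: LossParams = LossParams()) -> float:
    """(Tversky loss) ** gamma."""
    return tversky_loss(counts, params) ** params.gamma


def _tversky_value_grad(p, g, alpha, beta, smooth):
    """Tversky loss and its gradient w.r.t. p (shared by all three losses)."""
    tp = np.sum(p * g)
    fn = np.sum((1.0 - p) * g)
    fp = np.sum(p * (1.0 - g))
    num = tp + smooth
    den = tp + alpha * fn + beta * fp + smooth
    _check_defined(float(den))
    tl = 1.0 - num / den
    # d num/dp_i = g_i ; d den/dp_i = g_i - alpha*g_i + beta*(1-g_i)
    dden = g * (1.0 - alpha) + beta * (1.0 - g)
    dtl = -(g * den - num * dden) / (den * den)
    return float(tl), dtl


def loss_and_grad(name: str, prob_volume: np.ndarray, truth_mask: np.ndarray,
                  params: LossParams = LossParams()):
    """Loss value and analytic gradient d loss / d p for the training loop."""
    p = np.asarray(prob_volume, dtype=np.float64)
    g = np.asarray(truth_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if name == "dice":
        # Dice == Tversky(alpha = beta = 0.5) after rescaling num/den by 2;
        # the gradient is identical, the value too.
        return _tversky_value_grad(p, g, 0.5, 0.5, params.smooth / 2.0)
    if name == "tversky":
        return _tversky_value_grad(p, g, params.alpha, params.beta, params.smooth)
    if name == "focal_tversky":
        tl, dtl = _tversky_value_grad(p, g, params.alpha, params.beta, params.smooth)
        if tl == 0.0 and params.gamma < 1.0:
            raise FloatingPointError("focal gradient singular at TL = 0 for gamma < 1")
        value = tl ** params.gamma
        grad = params.gamma * (tl ** (params.gamma - 1.0)) * dtl if tl > 0 else 0.0 * dtl
        return value, grad
    raise ValueError(f"unknown loss {name!r}; expected one of {LOSS_NAMES}")
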