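"""Segmentation cost functions: class-balanced cross entropy and balanced
focal loss.

Both losses address severe class imbalance in CT slices.  The binary loss
weights foreground/background sums by the per-image multiplier

    beta = |Y^-| / |Y|,

and the multi-class balanced focal loss (BFL)

    BFL_n = - sum_s sum_{j in Y_n^s} beta_s (1 - P)^gamma log P,
    beta_s = exp(-|X_n^s| / |X_n|),

damps well-classified pixels through the modulating factor (1 - P)^gamma
and up-weights classes with a small per-image pixel share.  Natural
logarithms are used throughout; probabilities are clamped away from 0/1
before taking logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Loss selection and numerical parameters.

    mode : "cbce" (binary class-balanced cross entropy) or "bfl"
    gamma : focal modulating exponent, >= 0 (gamma=0 disables modulation)
    eps : probability clamp, 0 < eps < 1e-3
    """

    mode: str = "bfl"
    gamma: float = 2.0
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.mode not in ("cbce", "bfl"):
            raise ValueError(f"unknown loss mode {self.mode!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0.0 < self.eps < 1e-3):
            raise ValueError("eps must satisfy 0 < eps < 1e-3")


def _clamp(P: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(P, eps, 1.0 - eps)


def class_balanced_cross_entropy(
    P: np.ndarray, Y: np.ndarray, eps: float = DEFAULT_EPS
) -> float:
    """Binary class-balanced cross entropy for one image.

    Parameters
    ----------
    P : (H, W) foreground probabilities (sigmoid output)
    Y : (H, W) binary label map (1 = foreground set Y^+, 0 = Y^-)
    """
    P = _clamp(np.asarray(P, float), eps)
    Y = np.asarray(Y)
    if Y.size == 0:
        raise ValueError("empty image")
    beta = float((Y == 0).sum()) / Y.size
    pos = -beta * np.sum(np.log(P[Y == 1]))
    neg = -(1.0 - beta) * np.sum(np.log(1.0 - P[Y == 0]))
    return float(pos + neg)


def cbce_grad_logits(
    P: np.ndarray, Y: np.ndarray, eps: float = DEFAULT_EPS
) -> np.ndarray:
    """d CBCE / d logit for a sigmoid head (same shape as P)."""
    P = _clamp(np.asarray(P, float), eps)
    Y = np.asarray(Y)
    beta = float((Y == 0).sum()) / Y.size
    g = np.where(Y == 1, -beta * (1.0 - P), (1.0 - beta) * P)
    return g


def bfl_class_multipliers(Y_onehot: np.ndarray) -> np.ndarray:
    """Per-image class multipliers beta_s = exp(-|X^s|/|X|), shape (S,)."""
    Y = np.asarray(Y_onehot)
    n_pix = Y.shape[1] * Y.shape[2]
    share = Y.reshape(Y.shape[0], -1).sum(axis=1) / float(n_pix)
    return np.exp(-share)


def balanced_focal_loss(
    P_tensor: np.ndarray,
    Y_onehot: np.ndarray,
    cfg: LossConfig,
    class_multipliers: np.ndarray | None = None,
) -> float:
    """Balanced focal loss for one image.

    Parameters
    ----------
    P_tensor : (S, H, W) per-pixel class probabilities (softmax over S)
    Y_onehot : (S, H, W) one-hot true labels
    class_multipliers : (S,) overrides the per-image beta_s (e.g. all ones
        turns the gamma=0 loss into plain cross entropy)
    """
    P = np.asarray(P_tensor, float)
    Y = np.asarray(Y_onehot)
    if P.min() < 0 or P.max() > 1:
        raise ValueError("probabilities outside [0, 1]")
    P = _clamp(P, cfg.eps)
    beta = (
        np.asarray(class_multipliers, float)
        if class_multipliers is not None
        else bfl_class_multipliers(Y)
    )
    mask = Y == 1
    contrib = np.zeros_like(P)
    contrib[mask] = -((1.0 - P[mask]) ** cfg.gamma) * np.log(P[mask])
    return float(np.sum(beta[:, None, None] * contrib))


def bfl_grad_logits(
    P_tensor: np.ndarray, Y_onehot: np.ndarray, cfg: LossConfig
) -> np.ndarray:
    """d BFL / d softmax-logits, shape (S, H, W).

    For a pixel with true class c the loss depends on p_c only; the chain
    rule through the softmax gives
    dL/dz_k = (dL/dp_c) * p_c * (delta_{kc} - p_k).
    """
    P = _clamp(np.asarray(P_tensor, float), cfg.eps)
    Y = np.asarray(Y_onehot)
    beta = bfl_class_multipliers(Y)
    g = cfg.gamma
    # per-pixel dL/dp_c, laid out at the true-class slot
    pc = np.sum(P * Y, axis=0)  # (H, W)
    beta_c = np.einsum("s,shw->hw", beta, Y)
    one_m = 1.0 - pc
    if g == 0:
        dL_dpc = -beta_c / pc
    else:
        dL_dpc = beta_c * (g * one_m ** (g - 1.0) * np.log(pc) - one_m**g / pc)
    # softmax jacobian: dz_k = dL_dpc * pc * (Y_k - p_k)  [since delta_kc = Y_k]
    scale = dL_dpc * pc  # (H, W)
    return scale[None] * (Y - P)
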