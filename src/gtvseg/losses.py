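"""Dice + focal segmentation losses with deep-supervision weighting.

Each head (the main output and every auxiliary up-sampling path) is scored
with L_i = L_Dice + L_Focal on its softmax probabilities; the overall loss
is

    L = L_main + sum_i w_i * L_aux_i

with non-negative per-head weights w_i. Gradients with respect to the
logits are computed analytically (soft-Dice and focal derivatives composed
with the softmax Jacobian) so the network can be trained without an
autodiff framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Mask
from .model import ModelOutput
from .nn.functional import DTYPE, softmax_channels

__all__ = ["LossConfig", "LossValue", "dice_loss", "focal_loss", "composite_loss",
           "composite_loss_and_grads"]

_P_CLAMP = 1e-8


@dataclass(frozen=True)
class LossConfig:
    """head_weights are ordered fine-to-coarse over the auxiliary heads.

    The defaults (0.5, 0.25, 0.125) halve with depth — a conventional
    deep-supervision decay. focal_alpha is the foreground class-balance weight (0.5 =
    uniform); dice_smooth stabilizes the soft-Dice ratio.
    """

    head_weights: tuple = (0.5, 0.25, 0.125)
    focal_gamma: float = 2.0
    focal_alpha: float = 0.5
    dice_smooth: float = 1e-5

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.head_weights):
            raise ValueError("head weights must be non-negative")
        if self.dice_smooth <= 0 or self.focal_gamma < 0 or not (0 <= self.focal_alpha <= 1):
            raise ValueError(f"invalid loss config: {self}")

    def for_heads(self, n: int) -> "LossConfig":
        """Truncate/validate the weight list for a model with ``n`` aux heads."""
        if len(self.head_weights) < n:
            raise ValueError(f"need {n} head weights, have {len(self.head_weights)}")
        return LossConfig(tuple(self.head_weights[:n]), self.focal_gamma,
                          self.focal_alpha, self.dice_smooth)


@dataclass
class LossValue:
    """total = per_head[0].sum + sum_i weights[i] * per_head[i+1].sum."""

    total: float
    per_head: list  # [(dice, focal), ...], main head first then fine-to-coarse aux
    weights: tuple


def _target_array(target) -> np.ndarray:
    t = target.data if isinstance(target, Mask) else np.asarray(target)
    return t.astype(DTYPE)


def _check_probs(probs: np.ndarray, t: np.ndarray) -> None:
    if probs.ndim != 4 or probs.shape[1:] != t.shape:
        raise ValueError(f"probability grid {probs.shape} does not match target {t.shape}")


def dice_loss(probs: np.ndarray, target, smooth: float = 1e-5,
              with_grad: bool = False):
    """Soft Dice loss on the foreground channel: 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s)."""
    t = _target_array(target)
    _check_probs(probs, t)
    p1 = probs[1].astype(np.float64)
    num = 2.0 * float((p1 * t).sum()) + smooth
    den = float(p1.sum()) + float(t.sum()) + smooth
    loss = 1.0 - num / den
    if not with_grad:
        return loss
    # d/dp1 [1 - num/den]: num depends on p1 through 2*t, den through 1
    g1 = (num - 2.0 * t * den) / den**2
    grad = np.zeros_like(probs, dtype=np.float64)
    grad[1] = g1
    return loss, grad


def focal_loss(probs: np.ndarray, target, gamma: float = 2.0, alpha: float = 0.5,
               with_grad: bool = False):
    """Mean of -alpha_t * (1 - p_t)^gamma * log(p_t) over voxels.

    p_t is the predicted probability of the true class; alpha_t is
    ``alpha`` for foreground voxels and ``1 - alpha`` for background.
    Probabilities are clamped to [1e-8, 1 - 1e-8] so the loss and its
    gradient stay finite.
    """
    t = _target_array(target)
    _check_probs(probs, t)
    tmask = t > 0.5
    pt = np.where(tmask, probs[1], probs[0]).astype(np.float64)
    pt = np.clip(pt, _P_CLAMP, 1.0 - _P_CLAMP)
    at = np.where(tmask, alpha, 1.0 - alpha)
    one_minus = 1.0 - pt
    n = pt.size
    loss = float((at * one_minus**gamma * (-np.log(pt))).sum()) / n
    if not with_grad:
        return loss
    if gamma == 0.0:
        dpt = at * (-1.0 / pt) / n
    else:
        dpt = at * (gamma * one_minus ** (gamma - 1.0) * np.log(pt) - one_minus**gamma / pt) / n
    grad = np.zeros_like(probs, dtype=np.float64)
    grad[1] = np.where(tmask, dpt, 0.0)
    grad[0] = np.where(tmask, 0.0, dpt)
    return loss, grad


def _softmax_backward(probs: np.ndarray, gprobs: np.ndarray) -> np.ndarray:
    """VJP of the channel softmax: dz = p * (g - sum_c g_c p_c)."""
    p = probs.astype(np.float64)
    inner = (gprobs * p).sum(axis=0, keepdims=True)
    return (p * (gprobs - inner)).astype(DTYPE)


def _head_loss(logits, target, cfg: LossConfig, with_grad: bool):
    probs = softmax_channels(logits)
    if with_grad:
        d, gd = dice_loss(probs, target, cfg.dice_smooth, with_grad=True)
        f, gf = focal_loss(probs, target, cfg.focal_gamma, cfg.focal_alpha, with_grad=True)
        return (d, f), _softmax_backward(probs, gd + gf)
    d = dice_loss(probs, target, cfg.dice_smooth)
    f = focal_loss(probs, target, cfg.focal_gamma, cfg.focal_alpha)
    return (d, f), None


def composite_loss(out: ModelOutput, target, cfg: LossConfig) -> LossValue:
    """Deep-supervision loss over the main head and all auxiliary heads."""
    value, _, _ = _composite(out, target, cfg, with_grad=False)
    return value


def composite_loss_and_grads(out: ModelOutput, target, cfg: LossConfig):
    """Loss plus gradients w.r.t. (main_logits, [aux_logits...])."""
    return _composite(out, target, cfg, with_grad=True)


def _composite(out: ModelOutput, target, cfg: LossConfig, with_grad: bool):
    n_aux = len(out.aux_logits)
    if len(cfg.head_weights) != n_aux:
        raise ValueError(
            f"model has {n_aux} auxiliary heads but loss config carries "
            f"{len(cfg.head_weights)} head weights"
        )
    per_head = []
    (d, f), gmain = _head_loss(out.main_logits, target, cfg, with_grad)
    per_head.append((d, f))
    total = d + f
    gaux = []
    for w, logits in zip(cfg.head_weights, out.aux_logits):
        (d, f), g = _head_loss(logits, target, cfg, with_grad)
        per_head.append((d, f))
        total += w * (d + f)
        if with_grad:
            gaux.append((w * g).astype(DTYPE))
    value = LossValue(total=float(total), per_head=per_head, weights=tuple(cfg.head_weights))
    return value, gmain, gaux
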