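"""Combined cross-entropy + soft-Dice segmentation loss.

``loss = CE + (1 − mean over foreground classes of soft Dice)`` with

    Dice_c = (2 Σ p_c t_c + ε) / (Σ p_c + Σ t_c + ε),   ε = 1e-5,

where the sums run over all voxels of the batch and the mean excludes the
background class.  CE is the mean over voxels of −log p at the target
class.  The 1:1 weighting follows the standard recipe for segmentation
with heavy foreground/background imbalance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["soft_dice_ce_loss", "softmax_ce_dice_with_grad", "softmax"]

EPS_DICE = 1e-5
_CLAMP = 1e-12


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _one_hot(target: np.ndarray, n_classes: int, class_axis: int) -> np.ndarray:
    oh = np.eye(n_classes, dtype=np.float32)[target]
    return np.moveaxis(oh, -1, class_axis)


def soft_dice_ce_loss(pred_probs: np.ndarray, target: np.ndarray, class_axis: int = 0) -> float:
    """Loss from per-class probabilities (summing to 1 along ``class_axis``).

    ``target`` holds integer class labels with the class axis removed.
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    target = np.asarray(target)
    n_classes = p.shape[class_axis]
    if target.shape != tuple(s for i, s in enumerate(p.shape) if i != class_axis):
        raise ValueError(
            f"target shape {target.shape} incompatible with probabilities {p.shape}"
        )
    t = _one_hot(target, n_classes, class_axis).astype(np.float64)
    pt = np.take_along_axis(p, np.expand_dims(target, class_axis), axis=class_axis)
    ce = float(-np.log(np.clip(pt, _CLAMP, None)).mean())
    axes = tuple(i for i in range(p.ndim) if i != class_axis)
    inter = (p * t).sum(axis=axes)
    psum = p.sum(axis=axes)
    tsum = t.sum(axis=axes)
    dice = (2.0 * inter + EPS_DICE) / (psum + tsum + EPS_DICE)
    fg = [c for c in range(n_classes) if c != 0]
    return ce + (1.0 - float(dice[fg].mean()))


def softmax_ce_dice_with_grad(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the logits, for training.

    ``logits``: channels-last (B, D, H, W, C); ``target``: (B, D, H, W)
    integer labels.
    """
    p = softmax(logits.astype(np.float64), axis=-1)
    n_classes = logits.shape[-1]
    t = _one_hot(target, n_classes, -1).astype(np.float64)
    n_vox = target.size

    pt = np.take_along_axis(p, target[..., None], axis=-1)
    ce = float(-np.log(np.clip(pt, _CLAMP, None)).mean())

    axes = (0, 1, 2, 3)
    inter = (p * t).sum(axis=axes)
    psum = p.sum(axis=axes)
    tsum = t.sum(axis=axes)
    denom = psum + tsum + EPS_DICE
    dice = (2.0 * inter + EPS_DICE) / denom
    fg = np.arange(1, n_classes)
    loss = ce + (1.0 - float(dice[fg].mean()))

    # dL/dp: CE term −t/(p·N); Dice term −(1/K)·[2t·denom − (2·inter+ε)]/denom²
    dldp = -t / (np.clip(p, _CLAMP, None) * n_vox)
    k = len(fg)
    coef_t = np.zeros(n_classes)
    coef_const = np.zeros(n_classes)
    coef_t[fg] = 2.0 / (k * denom[fg])
    coef_const[fg] = (2.0 * inter[fg] + EPS_DICE) / (k * denom[fg] ** 2)
    dldp += -(coef_t * t) + coef_const

    # chain through softmax: dz = p ⊙ (g − Σ_c g_c p_c)
    inner = (dldp * p).sum(axis=-1, keepdims=True)
    dlogits = (p * (dldp - inner)).astype(logits.dtype)
    return loss, dlogits
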