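"""Focal classification loss, Dice segmentation loss, combined objective.

The per-image training objective is L = L_fl + lambda * L_ms, where
L_fl is the focal loss of the classification head for the true class v,

    L_fl = -alpha * (1 - p_v)^gamma * log(p_v),

and L_ms = 1 - D is the Dice loss of the segmentation head, with the
Dice coefficient D(w', w) = 2 |w ∩ w'| / (|w| + |w'|) computed softly
from the per-pixel class probabilities and averaged over the foreground
classes.  A smoothing constant (default 1.0) guards the 0/0 case of
empty masks inside the loss; reported (non-loss) Dice uses smooth = 0
with empty-vs-empty defined as 1.

Gradient helpers return derivatives with respect to the heads'
pre-softmax logits, with the softmax Jacobian folded in analytically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

_log = logging.getLogger("ihsnet")

_EPS = 1e-12


@dataclass(frozen=True)
class MultiTaskLoss:
    """Total loss L = L_fl + lambda * L_ms with its components."""

    l_fl: float
    l_ms: float
    lam: float

    @property
    def total(self) -> float:
        return self.l_fl + self.lam * self.l_ms


def focal_loss(
    pred_probs: np.ndarray,
    true_class: np.ndarray | int,
    gamma: float = 2.0,
    alpha: float = 0.25,
) -> float:
    """Mean focal loss -alpha (1-p_v)^gamma log p_v over a batch.

    ``pred_probs`` is (K,) or (N, K) of class probabilities summing to 1;
    ``true_class`` the true class index (or indices).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.atleast_2d(np.asarray(pred_probs, dtype=np.float64))
    v = np.atleast_1d(np.asarray(true_class, dtype=np.int64))
    pv = p[np.arange(p.shape[0]), v]
    if np.any(pv <= _EPS):
        _log.warning("focal loss: clamping %d zero probabilities", int((pv <= _EPS).sum()))
        pv = np.maximum(pv, _EPS)
    return float(np.mean(-alpha * (1.0 - pv) ** gamma * np.log(pv)))


def focal_loss_grad(
    pred_probs: np.ndarray,
    true_class: np.ndarray,
    gamma: float = 2.0,
    alpha: float = 0.25,
) -> tuple[float, np.ndarray]:
    """Focal loss and its gradient w.r.t. the pre-softmax logits."""
    p = np.asarray(pred_probs, dtype=np.float64)
    v = np.asarray(true_class, dtype=np.int64)
    n = p.shape[0]
    idx = np.arange(n)
    pv = np.maximum(p[idx, v], _EPS)
    loss = float(np.mean(-alpha * (1.0 - pv) ** gamma * np.log(pv)))
    # dL/dp_v, then through the softmax: dL/dz_k = dL/dp_v * p_v (delta - p_k)
    dldpv = -alpha * (
        -gamma * (1.0 - pv) ** np.maximum(gamma - 1.0, 0.0) * np.log(pv)
        + (1.0 - pv) ** gamma / pv
    )
    dlogits = -dldpv[:, None] * pv[:, None] * p
    dlogits[idx, v] += dldpv * pv
    return loss, (dlogits / n).astype(np.float32)


def dice_coefficient(
    pred: np.ndarray,
    target: np.ndarray,
    class_id: int | None = None,
    smooth: float = 0.0,
) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) for one class.

    ``pred`` may be a hard label map (then ``class_id`` selects the
    class) or an already-binary / soft [0,1] map; soft values weight the
    intersection.  With ``smooth == 0`` the empty-vs-empty case is
    defined as 1.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if class_id is not None:
        a = (pred == class_id).astype(np.float64)
        b = (target == class_id).astype(np.float64)
    else:
        a = pred.astype(np.float64)
        b = target.astype(np.float64)
    inter = float((a * b).sum())
    total = float(a.sum() + b.sum())
    if total == 0.0 and smooth == 0.0:
        return 1.0
    return (2.0 * inter + smooth) / (total + smooth)


def dice_loss(
    pred_probs: np.ndarray,
    target_labels: np.ndarray,
    smooth: float = 1.0,
    foreground_only: bool = True,
    mode: str = "image",
) -> float:
    """1 minus the mean soft Dice of the segmentation output.

    ``pred_probs`` is (N, C, H, W) per-pixel probabilities,
    ``target_labels`` (N, H, W) integer labels.  In ``"image"`` mode
    (default) Dice is computed per image over the background and the
    foreground classes present in that image, matching the per-input
    definition of the objective; in ``"batch"`` mode it is pooled over
    the batch per foreground class.  ``foreground_only=False`` averages
    over every channel instead.
    """
    loss, _ = dice_loss_grad(
        pred_probs, target_labels, smooth=smooth, foreground_only=foreground_only,
        mode=mode, with_grad=False,
    )
    return loss


def dice_loss_grad(
    pred_probs: np.ndarray,
    target_labels: np.ndarray,
    smooth: float = 1.0,
    foreground_only: bool = True,
    mode: str = "image",
    with_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Soft Dice loss and its gradient w.r.t. the segmentation logits."""
    if mode not in ("image", "batch"):
        raise ValueError(f"unknown dice mode {mode!r}")
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(target_labels)
    n, c = p.shape[0], p.shape[1]
    if t.shape != (n,) + p.shape[2:]:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {t.shape}")
    onehot = np.stack([(t == k).astype(np.float64) for k in range(c)], axis=1)

    if mode == "batch":
        cls = np.arange(1, c) if foreground_only else np.arange(c)
        inter = (p * onehot).sum(axis=(0, 2, 3))
        sums = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
        denom = sums + smooth
        dice = np.where(denom > 0, (2.0 * inter + smooth) / np.where(denom > 0, denom, 1.0), 1.0)
        loss = float(1.0 - dice[cls].mean())
        if not with_grad:
            return loss, None
        g = np.zeros_like(p)
        for k in cls:
            g[:, k] = -(2.0 * onehot[:, k] - dice[k]) / (sums[k] + smooth) / len(cls)
    else:
        # per image: Dice over the background channel and the foreground
        # classes present in that image (a wrong-class prediction then
        # always costs Dice somewhere, and an absent class cannot be
        # "scored" by simply predicting nothing)
        if foreground_only:
            weights = (onehot.sum(axis=(2, 3)) > 0).astype(np.float64)  # (n, c)
            weights[:, 0] = 1.0  # background always participates
        else:
            weights = np.ones((n, c))
        inter = (p * onehot).sum(axis=(2, 3))
        sums = p.sum(axis=(2, 3)) + onehot.sum(axis=(2, 3))
        pair_denom = sums + smooth
        dice = np.where(
            pair_denom > 0,
            (2.0 * inter + smooth) / np.where(pair_denom > 0, pair_denom, 1.0),
            1.0,
        )
        denom = weights.sum()
        loss = float(1.0 - (dice * weights).sum() / denom)
        if not with_grad:
            return loss, None
        g = (
            -(2.0 * onehot - dice[:, :, None, None])
            / (sums[:, :, None, None] + smooth)
            * weights[:, :, None, None]
            / denom
        )
    # through the per-pixel softmax: dL/dz = p * (g - sum_k g_k p_k)
    dlogits = p * (g - (g * p).sum(axis=1, keepdims=True))
    return loss, dlogits.astype(np.float32)


def multitask_loss(
    cls_probs: np.ndarray,
    seg_probs: np.ndarray,
    true_class: np.ndarray,
    true_mask: np.ndarray,
    lam: float = 1.0,
    gamma: float = 2.0,
    alpha: float = 0.25,
    smooth: float = 1.0,
    foreground_only: bool = True,
    dice_mode: str = "image",
) -> MultiTaskLoss:
    """Combined objective L = L_fl + lambda * L_ms for one batch."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    l_fl = focal_loss(cls_probs, true_class, gamma=gamma, alpha=alpha)
    l_ms = dice_loss(
        seg_probs, true_mask, smooth=smooth, foreground_only=foreground_only,
        mode=dice_mode,
    )
    return MultiTaskLoss(l_fl=l_fl, l_ms=l_ms, lam=lam)


def multitask_loss_grad(
    cls_probs: np.ndarray,
    seg_probs: np.ndarray,
    true_class: np.ndarray,
    true_mask: np.ndarray,
    lam: float = 1.0,
    gamma: float = 2.0,
    alpha: float = 0.25,
    smooth: float = 1.0,
    foreground_only: bool = True,
    dice_mode: str = "image",
) -> tuple[MultiTaskLoss, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. (segmentation logits, class logits)."""
    l_fl, d_cls = focal_loss_grad(cls_probs, true_class, gamma=gamma, alpha=alpha)
    l_ms, d_seg = dice_loss_grad(
        seg_probs, true_mask, smooth=smooth, foreground_only=foreground_only,
        mode=dice_mode,
    )
    return MultiTaskLoss(l_fl=l_fl, l_ms=l_ms, lam=lam), lam * d_seg, d_cls
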