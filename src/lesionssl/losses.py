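"""Supervised and consistency losses for voxel-wise lesion segmentation.

The supervised term combines a focal cross-entropy (to up-weight the rare
lesion voxels against the overwhelming background) with a soft-Dice term on
the foreground channel.  Negative cases are supervised against the
all-background mask, so the cohort's majority-negative structure actively
teaches the model what lesion-free tissue looks like.  The consistency term
is a mean squared difference between student and teacher foreground
probabilities on the original grid, with translation-border voxels excluded
through a validity mask.

Each public function returns the scalar loss; the ``*_grad`` companions also
return the gradient with respect to the foreground probability, which the
trainer routes through the softmax backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS_PROB = 1e-7
DICE_SMOOTH = 1e-5


@dataclass(frozen=True)
class LossReport:
    """Per-step loss decomposition: total = l_seg + lam * l_con."""

    l_seg: float
    l_con: float
    lam: float
    total: float
    step: int = 0

    def __post_init__(self):
        for name in ("l_seg", "l_con", "lam", "total"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite loss component {name}={v}")
        if self.l_seg < 0 or self.l_con < 0 or self.lam < 0:
            raise ValueError("loss components must be nonnegative")
        if abs(self.total - (self.l_seg + self.lam * self.l_con)) > 1e-5 * max(
                1.0, abs(self.total)):
            raise ValueError("total must equal l_seg + lam * l_con")


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS_PROB, 1.0 - EPS_PROB)


def focal_term(p_fg: np.ndarray, target: np.ndarray, gamma: float = 2.0,
               class_weight: float = 1.0) -> float:
    """Mean focal cross-entropy over the supplied voxels.

    Per voxel: ``-w * (1 - p_t)**gamma * log(p_t)`` where ``p_t`` is the
    probability assigned to the true class and ``w`` is ``class_weight`` for
    lesion voxels, 1 otherwise.  At ``gamma == 0`` and ``class_weight == 1``
    this is plain cross-entropy.
    """
    value, _ = focal_term_grad(p_fg, target, gamma, class_weight)
    return value


def focal_term_grad(p_fg: np.ndarray, target: np.ndarray, gamma: float = 2.0,
                    class_weight: float = 1.0):
    if gamma < 0:
        raise ValueError("focal gamma must be >= 0")
    p_fg = np.asarray(p_fg, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    p_t = _clamp(t * p_fg + (1.0 - t) * (1.0 - p_fg))
    w = np.where(t > 0, class_weight, 1.0)
    one_m = 1.0 - p_t
    log_pt = np.log(p_t)
    loss_vox = -w * one_m ** gamma * log_pt
    value = float(loss_vox.mean())
    # d/dp_t of -w (1-p_t)^g log p_t
    if gamma == 0:
        dpt = -w / p_t
    else:
        dpt = w * (gamma * one_m ** (gamma - 1) * log_pt - one_m ** gamma / p_t)
    sign = np.where(t > 0, 1.0, -1.0)  # p_t = p_fg for lesions, 1 - p_fg otherwise
    grad = dpt * sign / p_fg.size
    return value, grad


def soft_dice_grad(p_fg: np.ndarray, target: np.ndarray):
    """Soft-Dice loss (1 - Dice) of the foreground channel with its gradient."""
    p = np.asarray(p_fg, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum()) + DICE_SMOOTH
    num = 2.0 * inter + DICE_SMOOTH
    value = 1.0 - num / denom
    grad = -(2.0 * g * denom - num) / denom ** 2
    return value, grad


def segmentation_loss(p_fg: np.ndarray, mask: np.ndarray | None,
                      annotation_status: str, gamma: float = 2.0,
                      class_weight: float = 1.0, focal_weight: float = 1.0,
                      dice_weight: float = 1.0) -> float:
    """Supervised loss for one case: focal CE + soft Dice, equally weighted.

    Negative cases are supervised with the all-background mask.  Cases with
    status ``withheld_positive`` have no usable target and must not reach
    this function — they contribute only the consistency term.
    """
    value, _ = segmentation_loss_grad(p_fg, mask, annotation_status, gamma,
                                      class_weight, focal_weight, dice_weight)
    return value


def segmentation_loss_grad(p_fg, mask, annotation_status, gamma=2.0,
                           class_weight=1.0, focal_weight=1.0, dice_weight=1.0):
    if annotation_status == "withheld_positive" and mask is None:
        raise ValueError(
            "withheld_positive case has no released or pseudo mask; "
            "it contributes only the consistency loss")
    if mask is None:
        if annotation_status != "negative":
            raise ValueError(f"case with status {annotation_status!r} lacks a mask")
        mask = np.zeros(np.asarray(p_fg).shape, dtype=np.int16)
    target = (np.asarray(mask) > 0).astype(np.float64)
    f, df = focal_term_grad(p_fg, target, gamma, class_weight)
    d, dd = soft_dice_grad(p_fg, target)
    return focal_weight * f + dice_weight * d, focal_weight * df + dice_weight * dd


def consistency_loss(student_fg: np.ndarray, teacher_fg: np.ndarray,
                     valid_mask: np.ndarray | None = None) -> float:
    """Mean squared student-teacher difference over non-ignored voxels."""
    value, _ = consistency_loss_grad(student_fg, teacher_fg, valid_mask)
    return value


def consistency_loss_grad(student_fg, teacher_fg, valid_mask=None):
    s = np.asarray(student_fg, dtype=np.float64)
    t = np.asarray(teacher_fg, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError(f"misaligned shapes {s.shape} vs {t.shape}")
    if valid_mask is None:
        valid = np.ones(s.shape, dtype=bool)
    else:
        valid = np.asarray(valid_mask, dtype=bool)
        if valid.shape != s.shape:
            raise ValueError(f"valid mask shape {valid.shape} does not match {s.shape}")
    n = int(valid.sum())
    if n == 0:
        return 0.0, np.zeros_like(s)
    diff = np.where(valid, s - t, 0.0)
    value = float((diff * diff).sum() / n)
    grad = 2.0 * diff / n
    return value, grad


def sigmoid_ramp(step: int, total_ramp_steps: int, lam_max: float) -> float:
    """Sigmoid-shaped consistency-weight ramp, 0 -> lam_max over the ramp window."""
    if lam_max == 0.0:
        return 0.0
    if total_ramp_steps <= 0 or step >= total_ramp_steps:
        return lam_max
    x = np.clip(step / total_ramp_steps, 0.0, 1.0)
    return float(lam_max * np.exp(-5.0 * (1.0 - x) ** 2))
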