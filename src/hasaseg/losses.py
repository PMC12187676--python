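"""Hybrid segmentation loss: w1 * cross-entropy + w2 * soft Dice.

Cross-entropy treats every pixel as an independent categorical sample;
soft Dice measures per-class overlap between the predicted probability
channel and the one-hot target, so it stays informative for classes that
occupy few pixels.  With w1 = w2 = 0.5 (the default) the two terms are
balanced, which is the standard remedy for heavily imbalanced label maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossValue", "ce_loss", "dice_loss", "hybrid_loss", "one_hot"]

_CLAMP = 1e-7


@dataclass
class LossValue:
    """Total hybrid loss plus its two components (floats for logging)."""
    total: Tensor
    ce: float
    dice: float

    @property
    def value(self) -> float:
        return float(self.total.data)


def _as_prob_tensor(probs) -> Tensor:
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=float))
    if p.ndim == 3:
        p = p.reshape(1, *p.shape)
    if p.ndim != 4:
        raise ValueError(f"probs must be (K,H,W) or (N,K,H,W), got ndim={p.ndim}")
    return p


def _as_target(target, k: int) -> np.ndarray:
    t = np.asarray(target)
    if t.ndim == 2:
        t = t[None]
    if t.ndim != 3:
        raise ValueError(f"target must be (H,W) or (N,H,W), got ndim={t.ndim}")
    if not np.issubdtype(t.dtype, np.integer):
        raise ValueError("target must be an integer label map")
    if t.min() < 0 or t.max() >= k:
        raise ValueError(f"target labels must lie in [0, {k}), got "
                         f"[{t.min()}, {t.max()}]")
    return t


def one_hot(target: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W) integer labels -> (N,K,H,W) one-hot float array."""
    return np.moveaxis(np.eye(k)[target], -1, 1)


def ce_loss(probs, target, binary: bool = False) -> Tensor:
    """Mean pixel-wise cross-entropy.

    ``binary=False`` (default): categorical, ``-log p_true`` averaged over
    pixels.  ``binary=True``: the two-term foreground/background form
    ``-[y log p + (1-y) log(1-p)]`` with class 0 as background, averaged the
    same way (requires K = 2).  Probabilities are clamped at 1e-7 before the
    logarithm.
    """
    p = _as_prob_tensor(probs)
    k = p.shape[1]
    t = _as_target(target, k)
    oh = one_hot(t, k)
    logp = p.clamp_min(_CLAMP).log()
    npix = t.size
    if binary:
        if k != 2:
            raise ValueError("binary cross-entropy requires K=2")
        p_fg = p[:, 1]
        y = oh[:, 1]
        terms = (Tensor(y) * p_fg.clamp_min(_CLAMP).log()
                 + Tensor(1.0 - y) * (1.0 - p_fg).clamp_min(_CLAMP).log())
        return -terms.sum() * (1.0 / npix)
    return -(Tensor(oh) * logp).sum() * (1.0 / npix)


def dice_loss(probs, target, epsilon: float = 1.0,
              include_background: bool = True) -> Tensor:
    """Macro-averaged soft Dice loss, 1 - mean_c Dice_c.

    Per class c, Dice_c = (2 * sum y_c p_c + eps) / (sum y_c + sum p_c + eps)
    with sums pooled over all pixels of the batch.  The smoothing ``epsilon``
    (default 1) keeps classes absent from both prediction and target at
    Dice ~ 1 instead of 0/0.  ``include_background=False`` drops class 0
    from the average.
    """
    p = _as_prob_tensor(probs)
    k = p.shape[1]
    t = _as_target(target, k)
    oh = one_hot(t, k)
    start = 0 if include_background else 1
    n_classes = k - start
    total = None
    for c in range(start, k):
        pc = p[:, c]
        yc = Tensor(oh[:, c])
        inter = (pc * yc).sum()
        denom = pc.sum() + yc.sum()
        dice_c = (2.0 * inter + epsilon) / (denom + epsilon)
        total = dice_c if total is None else total + dice_c
    return 1.0 - total * (1.0 / n_classes)


def hybrid_loss(probs, target, w1: float = 0.5, w2: float = 0.5,
                dice_epsilon: float = 1.0, include_background: bool = True) -> LossValue:
    """``w1 * CE + w2 * Dice`` with both components reported."""
    if w1 < 0 or w2 < 0:
        raise ValueError("loss weights must be nonnegative")
    ce = ce_loss(probs, target)
    dice = dice_loss(probs, target, epsilon=dice_epsilon,
                     include_background=include_background)
    return LossValue(total=w1 * ce + w2 * dice,
                     ce=float(ce.data), dice=float(dice.data))
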