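"""Atrous Squeeze Attention (ASA) decoder head.

The head mixes multi-scale context into the decoder's last feature map:

1. **Atrous pyramid concat (APC)** — the C channels split into 4 equal
   groups; group *i* passes through a 3x3 atrous (dilated) convolution with
   dilation r_i (default 1/6/12/18, padding = dilation so spatial dims are
   preserved); outputs concatenate back to C channels.  The dilated pyramid
   reaches a 37-pixel receptive field at r=18 with 3x3-kernel cost.
2. **Squeeze-and-excitation (SE)** — global average pooling, then a
   bottleneck MLP C -> C/4 -> C producing per-channel logits.
3. **Softmax recalibration** — the logits normalize to a probability vector
   over channels, broadcast-multiplied onto the pyramid features.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import AsaConfig
from .hfef import _as_batched, _maybe_squeeze
from .nn import Tensor

__all__ = ["APC", "SqueezeExcite", "ASA", "softmax_recalibrate"]


class APC(nn.Module):
    """Grouped atrous convolution pyramid: group i gets dilation ``dilations[i]``."""

    def __init__(self, channels: int, cfg: AsaConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AsaConfig()
        if channels % cfg.groups:
            raise ValueError(f"C={channels} not divisible by groups={cfg.groups}")
        self.groups = cfg.groups
        self.dilations = tuple(cfg.dilations)
        per = channels // cfg.groups
        self.branches = nn.ModuleList([
            nn.Conv2d(per, per, cfg.kernel, dilation=r, rng=rng)
            for r in cfg.dilations
        ])

    def forward(self, x):
        xt, squeeze = _as_batched(x)
        c = xt.shape[1]
        per = c // self.groups
        outs = [branch(xt[:, i * per:(i + 1) * per])
                for i, branch in enumerate(self.branches)]
        return _maybe_squeeze(nn.concat(outs, axis=1), squeeze)


class SqueezeExcite(nn.Module):
    """Global average pool + bottleneck MLP; returns pre-softmax channel logits."""

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"C={channels} not divisible by reduction={reduction}")
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)

    def forward(self, f):
        ft, _ = _as_batched(f)
        z = ft.mean(axis=(2, 3))          # (N, C) squeeze
        return self.fc2(self.fc1(z).relu())


def softmax_recalibrate(z, scope: str = "full", groups: int = 4):
    """Normalize channel logits to attention weights summing to 1.

    ``scope='full'`` takes one softmax over all C channels; ``'per_group'``
    normalizes each of the ``groups`` channel blocks separately (each block
    then sums to 1).  Max-subtraction keeps the exponentials stable.
    """
    if not isinstance(z, Tensor):
        z = Tensor(np.asarray(z, dtype=float))
    squeeze = z.ndim == 1
    if squeeze:
        z = z.reshape(1, -1)
    if scope == "full":
        w = nn.softmax(z, axis=1)
    elif scope == "per_group":
        n, c = z.shape
        if c % groups:
            raise ValueError(f"C={c} not divisible by groups={groups}")
        w = nn.softmax(z.reshape(n, groups, c // groups), axis=2).reshape(n, c)
    else:
        raise ValueError(f"unknown softmax scope {scope!r}")
    return w.reshape(-1) if squeeze else w


class ASA(nn.Module):
    """APC features reweighted by softmax-normalized SE channel attention."""

    def __init__(self, channels: int, cfg: AsaConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg or AsaConfig()
        self.apc = APC(channels, self.cfg, rng=rng)
        self.se = SqueezeExcite(channels, self.cfg.reduction, rng=rng)

    def channel_weights(self, x):
        """The attention vector M_a for input ``x`` (one row per batch item)."""
        f = self.apc(x)
        return softmax_recalibrate(self.se(f), self.cfg.softmax_scope,
                                   self.cfg.groups)

    def forward(self, x):
        xt, squeeze = _as_batched(x)
        f = self.apc(xt)
        m = softmax_recalibrate(self.se(f), self.cfg.softmax_scope, self.cfg.groups)
        out = f * m.reshape(m.shape[0], m.shape[1], 1, 1)
        return _maybe_squeeze(out, squeeze)
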