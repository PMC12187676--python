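"""Hierarchical Feature Enhancement Fusion (HFEF).

The block enriches skip-connection and bottleneck features in three steps:

1. **Channel attention (CAB)** — a per-pixel channel MLP (1x1 convolutions
   C -> C/4 -> C with ReLU in between) whose sigmoid output gates the input
   channel-wise at every spatial position.
2. **Channel shuffle (CS)** — the deterministic interleaving permutation of
   grouped channels (reshape to (groups, C/groups), transpose, flatten) that
   lets information cross group boundaries.
3. **Spatial attention (SAB)** — a two-convolution bottleneck (C -> C/4 -> C)
   with batch normalization, whose sigmoid output gates the shuffled features.
   The convolution kernel grows with the hierarchy level (3/5/7/9 at levels
   1-4): shallow, high-resolution skips use small kernels for fine detail,
   deep ones large kernels for context.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import HfefConfig
from .nn import Tensor

__all__ = ["ChannelAttention", "SpatialAttention", "HFEF",
           "channel_shuffle", "shuffle_permutation"]


def _as_batched(x) -> tuple[Tensor, bool]:
    """Accept C,H,W or N,C,H,W (Tensor or ndarray); return N,C,H,W Tensor."""
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=float))
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected a 3-D or 4-D feature map, got ndim={x.ndim}")


def _maybe_squeeze(x: Tensor, squeeze: bool) -> Tensor:
    return x.reshape(*x.shape[1:]) if squeeze else x


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Index array pi with ``out[c] = in[pi[c]]`` for the shuffle."""
    if channels % groups:
        raise ValueError(f"C={channels} not divisible by groups={groups}")
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


def channel_shuffle(x, groups: int = 4):
    """Interleave channels across ``groups`` equal groups.

    Reshape the channel axis to (groups, C/groups), transpose, flatten: the
    output takes one channel from each group cyclically.  A bijection on
    channels; spatial content is untouched.
    """
    xt, squeeze = _as_batched(x)
    n, c, h, w = xt.shape
    if c % groups:
        raise ValueError(f"C={c} not divisible by groups={groups}")
    out = (xt.reshape(n, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(n, c, h, w))
    return _maybe_squeeze(out, squeeze)


class ChannelAttention(nn.Module):
    """CAB: sigmoid of a per-position channel MLP, multiplied onto the input.

    The 'linear layers' act along the channel axis independently at every
    pixel, i.e. 1x1 convolutions with a C/``reduction`` bottleneck.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"C={channels} not divisible by reduction={reduction}")
        self.fc1 = nn.Conv2d(channels, channels // reduction, 1, rng=rng)
        self.fc2 = nn.Conv2d(channels // reduction, channels, 1, rng=rng)

    def gate(self, x):
        xt, squeeze = _as_batched(x)
        m = self.fc2(self.fc1(xt).relu()).sigmoid()
        return _maybe_squeeze(m, squeeze)

    def forward(self, x):
        xt, squeeze = _as_batched(x)
        return _maybe_squeeze(xt * self.gate(xt), squeeze)


class SpatialAttention(nn.Module):
    """SAB: sigmoid(BN(conv_k(ReLU(BN(conv_k(x)))))) gating the input.

    Both k x k convolutions use symmetric zero padding (k-1)/2 so spatial
    dims are preserved; the first compresses to C/``reduction`` channels,
    the second restores C.  Convolutions carry no bias (each is followed by
    batch normalization).
    """

    def __init__(self, channels: int, kernel_size: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        if channels % reduction:
            raise ValueError(f"C={channels} not divisible by reduction={reduction}")
        mid = channels // reduction
        self.conv1 = nn.Conv2d(channels, mid, kernel_size, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, channels, kernel_size, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def gate(self, x):
        xt, squeeze = _as_batched(x)
        f = self.bn1(self.conv1(xt)).relu()
        m = self.bn2(self.conv2(f)).sigmoid()
        return _maybe_squeeze(m, squeeze)

    def forward(self, x):
        xt, squeeze = _as_batched(x)
        return _maybe_squeeze(xt * self.gate(xt), squeeze)


class HFEF(nn.Module):
    """CAB -> channel shuffle -> SAB, at one of four hierarchy levels."""

    def __init__(self, channels: int, level: int, cfg: HfefConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or HfefConfig()
        if channels % cfg.groups or channels % cfg.reduction:
            raise ValueError(
                f"C={channels} must be divisible by groups={cfg.groups} "
                f"and reduction={cfg.reduction}")
        self.level = level
        self.groups = cfg.groups
        self.kernel_size = cfg.kernel_for(level)
        self.cab = ChannelAttention(channels, cfg.reduction, rng=rng)
        self.sab = SpatialAttention(channels, self.kernel_size, cfg.reduction, rng=rng)

    def forward(self, x):
        xt, squeeze = _as_batched(x)
        out = self.sab(channel_shuffle(self.cab(xt), self.groups))
        return _maybe_squeeze(out, squeeze)
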