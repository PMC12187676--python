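"""HASA-ResUNet: residual-encoder U-Net with HFEF bridges and an ASA head.

Encoder: ``depth`` stages of residual blocks, 2x max pooling between stages,
channel width doubling per stage.  Decoder: kernel-2 stride-2 transposed
convolution, concatenation with the matching-scale skip, then two 3x3
conv+BN+ReLU layers.  The three highest-resolution skips pass through HFEF
levels 1-3 (kernels 3/5/7) and the bottleneck output through HFEF level 4
(kernel 9); the last decoder feature map passes through ASA before the 1x1
classification convolution and a per-pixel softmax over the K classes.
Both attention families can be switched off independently, which yields the
plain-ResUNet / +HFEF / +ASA / full ablation variants.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .config import ModelConfig
from .asa import ASA
from .hfef import HFEF
from .nn import Tensor

__all__ = ["ResidualBlock", "HasaResUNet", "build_model", "predict_mask",
           "save_checkpoint", "load_checkpoint"]


class ResidualBlock(nn.Module):
    """conv3x3-BN-ReLU-conv3x3-BN plus a shortcut, then ReLU.

    The shortcut is the identity when input and output channel counts match,
    otherwise a 1x1 projection convolution followed by batch normalization.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_channels)
        if in_channels == out_channels:
            self.shortcut = nn.Identity()
        else:
            self.shortcut = nn.Sequential([
                nn.Conv2d(in_channels, out_channels, 1, bias=False, rng=rng),
                nn.BatchNorm2d(out_channels),
            ])

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + self.shortcut(x)).relu()


class _DecoderStage(nn.Module):
    """Upsample, concatenate the skip, fuse with two conv-BN-ReLU layers."""

    def __init__(self, in_channels: int, skip_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        out = skip_channels
        self.up = nn.ConvTranspose2d(in_channels, out, rng=rng)
        self.conv1 = nn.Conv2d(out + skip_channels, out, 3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out)
        self.conv2 = nn.Conv2d(out, out, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out)

    def forward(self, x, skip):
        h = nn.concat([self.up(x), skip], axis=1)
        h = self.bn1(self.conv1(h)).relu()
        return self.bn2(self.conv2(h)).relu()


class HasaResUNet(nn.Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]

        def stage(cin, cout):
            blocks = [ResidualBlock(cin, cout, rng=rng)]
            blocks += [ResidualBlock(cout, cout, rng=rng)
                       for _ in range(cfg.blocks_per_stage - 1)]
            return nn.Sequential(blocks)

        self.encoder = nn.ModuleList(
            [stage(cfg.in_channels if i == 0 else widths[i - 1], widths[i])
             for i in range(cfg.depth)])
        self.pool = nn.MaxPool2d()

        if cfg.use_hfef:
            # levels 1-3 on the three highest-resolution skips, level 4 on
            # the bottleneck output
            n_skip_hfef = min(3, cfg.depth - 1)
            self.skip_hfef = nn.ModuleList(
                [HFEF(widths[i], i + 1, cfg.hfef, rng=rng)
                 for i in range(n_skip_hfef)])
            self.bottleneck_hfef = HFEF(widths[-1], 4, cfg.hfef, rng=rng)
        else:
            self.skip_hfef = nn.ModuleList([])
            self.bottleneck_hfef = nn.Identity()

        self.decoder = nn.ModuleList(
            [_DecoderStage(widths[i], widths[i - 1], rng=rng)
             for i in range(cfg.depth - 1, 0, -1)])

        self.asa = ASA(widths[0], cfg.asa, rng=rng) if cfg.use_asa else nn.Identity()
        self.head = nn.Conv2d(widths[0], cfg.num_classes, 1, rng=rng)

    # -- forward ----------------------------------------------------------
    def _check_input(self, x: Tensor) -> None:
        n, c, h, w = x.shape
        d = self.cfg.divisor
        if h % d or w % d:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by {d} "
                f"(2^(depth-1) with depth={self.cfg.depth})")
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {c}")
        if not np.all(np.isfinite(x.data)):
            raise ValueError("input contains NaN or Inf")

    def logits(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        self._check_input(x)
        skips = []
        h = x
        for i, enc in enumerate(self.encoder):
            h = enc(h)
            if i < self.cfg.depth - 1:
                skips.append(h)
                h = self.pool(h)
        h = self.bottleneck_hfef(h)
        for i in range(len(self.skip_hfef)):
            skips[i] = self.skip_hfef[i](skips[i])
        for dec, skip in zip(self.decoder, reversed(skips)):
            h = dec(h, skip)
        return self.head(self.asa(h))

    def forward(self, x) -> Tensor:
        """Per-pixel class probabilities, shape (N, K, H, W)."""
        return nn.softmax(self.logits(x), axis=1)


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> HasaResUNet:
    """Construct the network with seeded He-normal initialization."""
    return HasaResUNet(cfg or ModelConfig(), seed=seed)


def predict_mask(model: HasaResUNet, images: np.ndarray) -> np.ndarray:
    """Argmax label maps for a batch (N,1,H,W) or single image (1,H,W).

    Ties break to the lowest class index (NumPy argmax convention).
    """
    arr = np.asarray(images, dtype=float)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains NaN or Inf")
    model.eval()
    with nn.no_grad():
        probs = model(Tensor(arr)).data
    labels = probs.argmax(axis=1).astype(np.uint8)
    return labels[0] if single else labels


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(path: str | Path, model: HasaResUNet) -> None:
    """Parameters + buffers + config + seed in one ``.npz`` file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"config": _cfg_to_dict(model.cfg), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | Path) -> HasaResUNet:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(_cfg_from_dict(meta["config"]), seed=meta["seed"])
    model.load_state_dict(state)
    return model


def _cfg_to_dict(cfg: ModelConfig) -> dict:
    import dataclasses
    return dataclasses.asdict(cfg)


def _cfg_from_dict(d: dict) -> ModelConfig:
    from .config import AsaConfig, HfefConfig
    d = dict(d)
    d["hfef"] = HfefConfig(**{**d.get("hfef", {}),
                              "kernels": tuple(d.get("hfef", {}).get("kernels", (3, 5, 7, 9)))})
    asa_d = dict(d.get("asa", {}))
    if "dilations" in asa_d:
        asa_d["dilations"] = tuple(asa_d["dilations"])
    d["asa"] = AsaConfig(**asa_d)
    return ModelConfig(**d)
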