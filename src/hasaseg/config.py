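"""Configuration dataclasses and YAML loading.

All knobs that the attention blocks, network, loss, augmentation, phantom
generator and training loop expose live here, with the defaults used in the
full-scale setup; ``tiny()`` presets shrink widths and resolution for CPU
experimentation and the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "HfefConfig", "AsaConfig", "ModelConfig", "LossConfig",
    "AugmentConfig", "TrainConfig", "load_yaml_config",
]


@dataclass
class HfefConfig:
    """Hierarchical feature-enhancement fusion block settings.

    ``kernels[level-1]`` is the spatial-attention kernel at hierarchy level
    1-4 (shallow levels get small kernels, 2*level + 1 by default).
    """
    groups: int = 4
    reduction: int = 4
    kernels: tuple[int, int, int, int] = (3, 5, 7, 9)

    def kernel_for(self, level: int) -> int:
        if level not in (1, 2, 3, 4):
            raise ValueError(f"HFEF level must be 1..4, got {level}")
        k = self.kernels[level - 1]
        if k % 2 == 0:
            raise ValueError(f"HFEF kernel must be odd, got {k}")
        return k


@dataclass
class AsaConfig:
    """Atrous squeeze-attention head settings."""
    groups: int = 4
    dilations: tuple[int, ...] = (1, 6, 12, 18)
    kernel: int = 3
    reduction: int = 4
    softmax_scope: str = "full"  # "full" | "per_group"

    def __post_init__(self):
        if len(self.dilations) != self.groups:
            raise ValueError(
                f"need one dilation per group: {len(self.dilations)} dilations "
                f"for {self.groups} groups")
        if self.kernel % 2 == 0:
            raise ValueError("ASA kernel must be odd")
        if self.softmax_scope not in ("full", "per_group"):
            raise ValueError(f"unknown softmax_scope {self.softmax_scope!r}")


@dataclass
class ModelConfig:
    in_channels: int = 1
    num_classes: int = 11
    base_channels: int = 64
    depth: int = 5                 # resolution levels: depth-1 downsamplings
    blocks_per_stage: int = 2
    use_hfef: bool = True
    use_asa: bool = True
    hfef: HfefConfig = field(default_factory=HfefConfig)
    asa: AsaConfig = field(default_factory=AsaConfig)

    def __post_init__(self):
        if self.base_channels % 4:
            raise ValueError("base_channels must be divisible by 4")
        if self.depth < 2:
            raise ValueError("depth must be at least 2")

    @property
    def divisor(self) -> int:
        """Spatial dims must be divisible by this (2^(depth-1))."""
        return 2 ** (self.depth - 1)

    @classmethod
    def tiny(cls, use_hfef: bool = True, use_asa: bool = True) -> "ModelConfig":
        """CPU-scale preset: widths 8..128, one residual block per stage."""
        return cls(base_channels=8, depth=5, blocks_per_stage=1,
                   use_hfef=use_hfef, use_asa=use_asa)


@dataclass
class LossConfig:
    w1: float = 0.5                # cross-entropy weight
    w2: float = 0.5                # Dice weight
    dice_epsilon: float = 1.0
    include_background: bool = True

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class AugmentConfig:
    """Online augmentation: rotation, Gaussian noise, elastic warp, brightness.

    Geometric transforms hit image and mask identically (mask resampled with
    nearest neighbor); intensity transforms hit the image only.
    """
    rotation_deg: float = 15.0
    gauss_noise_sigma: float = 0.05      # fraction of the image intensity std
    elastic_alpha: float = 34.0
    elastic_sigma: float = 4.0
    brightness: float = 0.10             # fractional intensity shift
    probability: float = 0.5             # per-transform application probability

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 6
    max_epochs: int = 100
    early_stop_patience: int = 5
    min_delta: float = 1e-5
    monitor_background: bool = False     # include class 0 in the monitored DSC
    seed: int = 0
    checkpoint_dir: str | None = None
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")

    @classmethod
    def tiny(cls, **kw) -> "TrainConfig":
        return cls(batch_size=4, **kw)


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            raise KeyError(f"unknown {cls.__name__} key {key!r}")
        ftype = fields[key].type
        if isinstance(val, dict) and ftype in ("HfefConfig", "AsaConfig",
                                               "AugmentConfig", "LossConfig"):
            val = _build(globals()[ftype], val)
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


def load_yaml_config(path: str | Path) -> dict:
    """Read a YAML file with optional ``model:`` / ``train:`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    if "model" in raw:
        out["model"] = _build(ModelConfig, raw["model"])
    if "train" in raw:
        out["train"] = _build(TrainConfig, raw["train"])
    return out
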