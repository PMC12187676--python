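"""Layer abstractions over the autodiff core (Module, Conv2d, BatchNorm2d, ...)."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (Tensor, batch_norm, concat, conv2d, conv_transpose2x2,
                     maxpool2x2)

__all__ = [
    "Parameter", "Module", "Sequential", "ModuleList", "Identity",
    "Conv2d", "ConvTranspose2d", "Linear", "BatchNorm2d", "ReLU",
    "Sigmoid", "MaxPool2d",
]


class Parameter(Tensor):
    """A leaf tensor registered by :class:`Module` and updated by optimizers."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter/buffer discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal --------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                sub = f"{prefix}.{name}" if prefix else name
                yield from attr.named_modules(sub)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules():
            for name, attr in vars(mod).items():
                if isinstance(attr, Parameter):
                    yield (f"{mod_name}.{name}" if mod_name else name), attr

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for mod_name, mod in self.named_modules():
            for name in getattr(mod, "_buffers", ()):
                arr = getattr(mod, name)
                yield (f"{mod_name}.{name}" if mod_name else name), arr

    # -- modes ------------------------------------------------------------
    def train(self) -> "Module":
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for _, m in self.named_modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data = np.asarray(arr, dtype=own[name].data.dtype).copy()
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected state entry {name}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def append(self, m: Module) -> None:
        setattr(self, str(len(self)), m)

    def __len__(self) -> int:
        return sum(isinstance(v, Module) for k, v in vars(self).items() if k.isdigit())

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(len(self)))

    def __getitem__(self, i: int) -> Module:
        return getattr(self, str(i % len(self) if i < 0 else i))


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    """2x2, stride-2 max pooling."""

    def forward(self, x):
        return maxpool2x2(x)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Stride-1 2-D convolution with 'same'-style symmetric zero padding.

    ``padding=None`` selects ``(k-1)//2 * dilation`` so spatial dims are
    preserved. He-normal weight init, zero bias.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int | None = None, dilation: int = 1, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        if in_channels % groups:
            raise ValueError("in_channels not divisible by groups")
        rng = rng or np.random.default_rng()
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.groups = groups
        self.padding = (kernel_size - 1) // 2 * dilation if padding is None else padding
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(_he_normal(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        out = conv2d(x, self.weight, padding=self.padding,
                     dilation=self.dilation, groups=self.groups)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class ConvTranspose2d(Module):
    """Kernel-2, stride-2 transposed convolution (doubles H and W)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_normal(
            rng, (in_channels, out_channels, 2, 2), in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x):
        return conv_transpose2x2(x, self.weight) + self.bias.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_normal(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x):
        return batch_norm(x, self.weight, self.bias, self.running_mean,
                          self.running_var, self.training, self.momentum, self.eps)
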