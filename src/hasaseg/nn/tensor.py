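"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ``numpy.ndarray`` together with an optional
gradient and a closure computing vector-Jacobian products for its parents.
The op set is exactly what a 2-D segmentation network needs: broadcasting
arithmetic, matmul, activations, reductions, shape ops, stride-1 (dilated,
grouped) convolution, 2x2 transposed convolution, 2x2 max pooling, batch
normalization and softmax.  Convolutions are evaluated by ``im2col`` +
BLAS matmul; the input gradient of a convolution is itself a convolution
with the spatially flipped kernel, so no scatter-add is ever needed.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "batch_norm",
    "softmax",
    "set_default_dtype",
    "default_dtype",
    "using_dtype",
]

_GRAD_ENABLED = True

# float32 is the working precision for training (the standard for CNNs);
# float64 is available for oracle comparisons and finite-difference checks.
_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = np.dtype(dtype).type


def default_dtype():
    return _DTYPE


@contextlib.contextmanager
def using_dtype(dtype):
    """Temporarily change the dtype new tensors are created with."""
    prev = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A differentiable array node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], Sequence[np.ndarray | None]]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = parents
            out._backward = backward
        return out

    # -- misc -------------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd engine --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if parent._backward is None:
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor._make(a + b, (self, other),
                            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor._make(a * b, (self, other),
                            lambda g: (_unbroadcast(g * b, a.shape),
                                       _unbroadcast(g * a, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor._make(a / b, (self, other),
                            lambda g: (_unbroadcast(g / b, a.shape),
                                       _unbroadcast(-g * a / (b * b), b.shape)))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self.data
        return Tensor._make(a ** p, (self,), lambda g: (g * p * a ** (p - 1),))

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor._make(a @ b, (self, other),
                            lambda g: (g @ b.T, a.T @ g))

    # -- activations ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(np.where(mask, self.data, 0.0), (self,),
                            lambda g: (g * mask,))

    def sigmoid(self):
        y = expit(self.data)
        return Tensor._make(y, (self,), lambda g: (g * y * (1.0 - y),))

    def exp(self):
        y = np.exp(self.data)
        return Tensor._make(y, (self,), lambda g: (g * y,))

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        y = np.sqrt(self.data)
        return Tensor._make(y, (self,), lambda g: (g / (2.0 * y),))

    def clamp_min(self, lo: float):
        """Lower clip; gradient passes only where the input is above ``lo``."""
        mask = self.data > lo
        return Tensor._make(np.maximum(self.data, lo), (self,),
                            lambda g: (g * mask,))

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self.data
        out = a.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g
            if not keepdims:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(ax % a.ndim for ax in axes)
                for ax in sorted(axes):
                    gg = np.expand_dims(gg, ax)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        a = self.data
        n = a.size if axis is None else np.prod(
            [a.shape[ax % a.ndim] for ax in ((axis,) if np.isscalar(axis) else axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self.data
        return Tensor._make(a.reshape(shape), (self,),
                            lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, key):
        a = self.data

        def backward(g):
            full = np.zeros_like(a)
            full[key] = g
            return (full,)

        return Tensor._make(a[key], (self,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution and friends
# ---------------------------------------------------------------------------

def _im2col_mat(x: np.ndarray, k: int, padding: int, dilation: int
                ) -> tuple[np.ndarray, int, int]:
    """Windows of ``x`` (N,C,H,W) as a contiguous (N*Ho*Wo, C*k*k) matrix."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    eff = (k - 1) * dilation + 1
    win = sliding_window_view(x, (eff, eff), axis=(2, 3))
    if dilation > 1:
        win = win[..., ::dilation, ::dilation]
    n, _, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
    return np.ascontiguousarray(cols), ho, wo


def _conv_piece(xd: np.ndarray, wd: np.ndarray, padding: int, dilation: int):
    """Forward conv for one group; returns (out, cached im2col matrix)."""
    o, _, k, _ = wd.shape
    cols, ho, wo = _im2col_mat(xd, k, padding, dilation)
    out = cols @ wd.reshape(o, -1).T
    out = out.reshape(xd.shape[0], ho, wo, o).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), cols


def conv2d(x: Tensor, w: Tensor, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), ``w``: (O, C/groups, k, k).

    The im2col matrix built in the forward pass is kept for the weight
    gradient; the input gradient is the convolution of the output gradient
    with the spatially flipped, channel-transposed kernel.
    """
    xd, wd = x.data, w.data
    n, c, _, _ = xd.shape
    o, cg, k, _ = wd.shape
    if c % groups or o % groups or cg != c // groups:
        raise ValueError(f"channel/group mismatch: C={c}, O={o}, groups={groups}, "
                         f"kernel expects {cg} input channels per group")

    cs, os_ = c // groups, o // groups
    if groups == 1:
        out, cols = _conv_piece(xd, wd, padding, dilation)
        cols_list = [cols] if _GRAD_ENABLED else None
    else:
        outs, cols_list = [], ([] if _GRAD_ENABLED else None)
        for gi in range(groups):
            og, cg_cols = _conv_piece(xd[:, gi * cs:(gi + 1) * cs],
                                      wd[gi * os_:(gi + 1) * os_],
                                      padding, dilation)
            outs.append(og)
            if cols_list is not None:
                cols_list.append(cg_cols)
        out = np.concatenate(outs, axis=1)

    def backward(g):
        pad_b = (k - 1) * dilation - padding
        gws, gxs = [], []
        for gi in range(groups):
            gs = np.ascontiguousarray(g[:, gi * os_:(gi + 1) * os_]) \
                if groups > 1 else np.ascontiguousarray(g)
            ws = wd[gi * os_:(gi + 1) * os_] if groups > 1 else wd
            go_mat = gs.transpose(0, 2, 3, 1).reshape(-1, os_ if groups > 1 else o)
            gws.append((go_mat.T @ cols_list[gi]).reshape(ws.shape))
            w_flip = np.ascontiguousarray(ws[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            gxs.append(_conv_piece(gs, w_flip, pad_b, dilation)[0])
        gw = gws[0] if groups == 1 else np.concatenate(gws, axis=0)
        gx = gxs[0] if groups == 1 else np.concatenate(gxs, axis=1)
        return gx, gw

    return Tensor._make(out, (x, w), backward)


def conv_transpose2x2(x: Tensor, w: Tensor) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    ``w``: (C_in, C_out, 2, 2); output pixel (2i+a, 2j+b) receives
    ``sum_c x[c,i,j] * w[c,o,a,b]`` — windows never overlap.
    """
    xd, wd = x.data, w.data
    n, c, h, ww_ = xd.shape
    o = wd.shape[1]
    tmp = np.tensordot(xd, wd, axes=([1], [0]))          # (N,H,W,O,2,2)
    out = np.ascontiguousarray(tmp.transpose(0, 3, 1, 4, 2, 5)) \
            .reshape(n, o, 2 * h, 2 * ww_)

    def backward(g):
        g6 = np.ascontiguousarray(
            g.reshape(n, o, h, 2, ww_, 2).transpose(0, 2, 4, 1, 3, 5))  # (N,H,W,O,2,2)
        gx = np.ascontiguousarray(
            np.tensordot(g6, wd, axes=([3, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2))
        gw = np.tensordot(xd, g6, axes=([0, 2, 3], [0, 1, 2]))
        return gx, gw

    return Tensor._make(out, (x, w), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties resolve to the first (row-major) element."""
    xd = x.data
    n, c, h, w = xd.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    win = xd.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
                 .reshape(n, c, h, w)
        return (gx,)

    return Tensor._make(out, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode batch statistics normalize and the running buffers are
    updated in place (unbiased variance, torch convention); in inference mode
    the running buffers normalize.
    """
    xd = x.data
    n, c, h, w = xd.shape
    gd = gamma.data.reshape(1, c, 1, 1)
    if training:
        m = n * h * w
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * (var * m / max(m - 1, 1))
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (xd - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        out = gd * xhat + beta.data.reshape(1, c, 1, 1)

        def backward(g):
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            gmean = g.mean(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            gxhat_mean = (g * xhat).mean(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            gx = gd * inv.reshape(1, c, 1, 1) * (g - gmean - xhat * gxhat_mean)
            return gx, dgamma, dbeta

    else:
        inv = (1.0 / np.sqrt(running_var + eps)).astype(xd.dtype)
        xhat = (xd - running_mean.astype(xd.dtype).reshape(1, c, 1, 1)) \
            * inv.reshape(1, c, 1, 1)
        out = gd * xhat + beta.data.reshape(1, c, 1, 1)

        def backward(g):
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            gx = g * gd * inv.reshape(1, c, 1, 1)
            return gx, dgamma, dbeta

    return Tensor._make(out, (x, gamma, beta), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stabilized softmax along ``axis``."""
    xd = x.data
    z = xd - xd.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    return Tensor._make(y, (x,), backward)
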