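"""A compact reverse-mode automatic-differentiation engine on NumPy.

This module provides the tensor, layer and optimizer primitives the rest of
the package is built on: broadcasting arithmetic, batched matmul, 2-D
convolution and pooling, embeddings, batch/layer normalization, and an Adam
optimizer.  It deliberately covers only what the segmentation networks and
their training losses need; everything is plain float NumPy, single device,
and deterministic given seeded initialization.

Gradients follow the usual conventions: subgradient 0 at ReLU kinks, ties in
max reductions routed to the first maximal entry (pairwise maxima route to
the left operand), so repeated runs are bit-identical.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

# Default parameter / activation dtype.  float32 keeps BLAS fast; tests that
# finite-difference the gradients temporarily switch to float64.
DEFAULT_DTYPE = np.float32

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation / EMA updates)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = _backward
        self._prev = _prev if self.requires_grad else ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = grad.astype(self.data.dtype, copy=False)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray, fresh: bool = False) -> None:
        """Accumulate a gradient contribution.

        `fresh` marks arrays the caller newly allocated and does not alias
        anywhere else, which may be adopted without a defensive copy.
        """
        if self.grad is None:
            if fresh and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    gs = _unbroadcast(g, self.data.shape)
                    self._accum(gs, fresh=gs is not g)
                if other.requires_grad:
                    go = _unbroadcast(g, other.data.shape)
                    other._accum(go, fresh=go is not g)
            out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape),
                                fresh=True)
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape),
                                 fresh=True)
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other, self.data.dtype) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(g * p * self.data ** (p - 1.0), fresh=True)
            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    gx = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accum(_unbroadcast(gx, self.data.shape), fresh=True)
                if other.requires_grad:
                    gw = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accum(_unbroadcast(gw, other.data.shape), fresh=True)
            out._backward = _bw
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(g * out.data, fresh=True)
            out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(g / self.data, fresh=True)
            out._backward = _bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        if out.requires_grad:
            mask = self.data > 0

            def _bw(g):
                self._accum(g * mask, fresh=True)
            out._backward = _bw
        return out

    def leaky_relu(self, alpha: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data),
                     self.requires_grad, (self,))
        if out.requires_grad:
            slope = np.where(self.data > 0, 1.0, alpha).astype(self.data.dtype)

            def _bw(g):
                self._accum(g * slope, fresh=True)
            out._backward = _bw
        return out

    def sigmoid(self):
        # numerically stable split by sign
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -60, None))),
                     np.exp(np.clip(x, None, 60)) / (1.0 + np.exp(np.clip(x, None, 60))))
        s = s.astype(x.dtype)
        out = Tensor(s, self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(g * s * (1.0 - s), fresh=True)
            out._backward = _bw
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))
        if out.requires_grad:
            mask = (self.data >= lo) & (self.data <= hi)

            def _bw(g):
                self._accum(g * mask, fresh=True)
            out._backward = _bw
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(g.reshape(self.data.shape))
            out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(g.transpose(inv))
            out._backward = _bw
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis).copy(), self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(np.flip(g, axis=axis))
            out._backward = _bw
        return out

    def rot90(self, k: int, axes: tuple[int, int] = (-2, -1)):
        out = Tensor(np.rot90(self.data, k=k, axes=axes).copy(),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                self._accum(np.rot90(g, k=-k, axes=axes))
            out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full, fresh=True)
            out._backward = _bw
        return out

    def pad2d(self, p: int):
        """Zero-pad the last two axes by `p` on every side."""
        if p == 0:
            return self
        width = [(0, 0)] * (self.data.ndim - 2) + [(p, p), (p, p)]
        out = Tensor(np.pad(self.data, width), self.requires_grad, (self,))
        if out.requires_grad:
            sl = (Ellipsis, slice(p, -p), slice(p, -p))

            def _bw(g):
                self._accum(g[sl])
            out._backward = _bw
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape))
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient routed to the first maximal entry."""
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
                self._accum(full, fresh=True)
            out._backward = _bw
        return out

    def maximum(self, other):
        """Elementwise max; ties route gradient to `self`."""
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(np.maximum(self.data, other.data),
                     self.requires_grad or other.requires_grad, (self, other))
        if out.requires_grad:
            left = self.data >= other.data

            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * left, self.data.shape),
                                fresh=True)
                if other.requires_grad:
                    other._accum(_unbroadcast(g * ~left, other.data.shape),
                                 fresh=True)
            out._backward = _bw
        return out


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype or DEFAULT_DTYPE))


def tensor(x, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(x, dtype=DEFAULT_DTYPE), requires_grad=requires_grad)


def concatenate(tensors: Sequence[Tensor], axis: int) -> Tensor:
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused, shift-stabilized softmax with the analytic Jacobian product."""
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        def _bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum((g - dot) * y, fresh=True)
        out._backward = _bw
    return out


def stack0(tensors: Sequence[Tensor]) -> Tensor:
    return concatenate([t.reshape((1,) + t.shape) for t in tensors], axis=0)


# ---------------------------------------------------------------------------
# Structured ops: convolution, pooling, resampling, embedding
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, square stride/pad."""
    B, Cin, H, W = x.shape
    Cout, Cin2, kh, kw = w.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d channel mismatch: {Cin} vs {Cin2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                       # B,Cin,Ho,Wo,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, Cin * kh * kw)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    y = np.matmul(cols, wmat.T)                               # B,HoWo,Cout
    if b is not None:
        y = y + b.data
    y = y.transpose(0, 2, 1).reshape(B, Cout, Ho, Wo)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, req, prev)
    if out.requires_grad:
        cols_saved = cols if w.requires_grad else None

        def _bw(g):
            g2 = g.reshape(B, Cout, Ho * Wo).transpose(0, 2, 1)   # B,HoWo,Cout
            if b is not None and b.requires_grad:
                b._accum(g2.sum(axis=(0, 1)), fresh=True)
            if w.requires_grad:
                gw = np.einsum("bnc,bnk->ck", g2, cols_saved)
                w._accum(gw.reshape(w.data.shape), fresh=True)
            if x.requires_grad:
                gcols = np.matmul(g2, wmat)                        # B,HoWo,Cin*kh*kw
                gcols = gcols.reshape(B, Ho, Wo, Cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                gxp = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        gxp[:, :, ki:ki + Ho * stride:stride,
                            kj:kj + Wo * stride:stride] += gcols[:, :, :, :, ki, kj]
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accum(gxp, fresh=True)
        out._backward = _bw
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling (NCHW); dims must divide by k."""
    B, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"maxpool2d: dims {(H, W)} not divisible by {k}")
    r = x.reshape(B, C, H // k, k, W // k, k).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(B, C, H // k, W // k, k * k)
    return r.amax(axis=-1)


def maxpool3x3_s1(x: Tensor) -> Tensor:
    """3x3 max pooling, stride 1, zero padding (dims preserved)."""
    p = x.pad2d(1)
    H, W = x.shape[-2], x.shape[-1]
    out = None
    for di in range(3):
        for dj in range(3):
            piece = p[..., di:di + H, dj:dj + W]
            out = piece if out is None else out.maximum(piece)
    return out


def upsample_nearest(x: Tensor, s: int = 2) -> Tensor:
    B, C, H, W = x.shape
    d = np.repeat(np.repeat(x.data, s, axis=2), s, axis=3)
    out = Tensor(d, x.requires_grad, (x,))
    if out.requires_grad:
        def _bw(g):
            g = g.reshape(B, C, H, s, W, s).sum(axis=(3, 5))
            x._accum(g, fresh=True)
        out._backward = _bw
    return out


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    out = Tensor(table.data[ids], table.requires_grad, (table,))
    if out.requires_grad:
        def _bw(g):
            full = np.zeros_like(table.data)
            np.add.at(full, ids, g)
            table._accum(full, fresh=True)
        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DEFAULT_DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = []
        for name, p in self._params.items():
            out.append((prefix + name, p))
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def modules(self) -> Iterable["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ---- persistence -----------------------------------------------------
    def _buffers(self) -> dict[str, np.ndarray]:
        """Override in subclasses that carry non-parameter state."""
        return {}

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: p.data.copy() for k, p in self._params.items()}
        for k, v in self._buffers().items():
            out[prefix + k] = v.copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=p.data.dtype).copy()
        for k, v in self._buffers().items():
            v[...] = state[prefix + k]
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def architecture_summary(self) -> list[str]:
        """Layer-type / parameter-shape fingerprint (ignores values)."""
        return [f"{n}:{tuple(p.data.shape)}" for n, p in self.named_parameters()]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods: Sequence[Module] = ()):  # noqa: D401
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        name = str(len(self._list))
        self._list.append(m)
        self._modules[name] = m
        object.__setattr__(self, name, m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DEFAULT_DTYPE)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_he_normal(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        object.__setattr__(self, "running_mean", np.zeros(c, dtype=np.float64))
        object.__setattr__(self, "running_var", np.ones(c, dtype=np.float64))

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var[...] = (1 - m) * self.running_var + m * var.data.ravel()
            xn = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.astype(x.data.dtype).reshape(1, c, 1, 1))
            var = Tensor(self.running_var.astype(x.data.dtype).reshape(1, c, 1, 1))
            xn = (x - mu) * (var + self.eps) ** -0.5
        g = self.gamma.reshape(1, c, 1, 1)
        b = self.beta.reshape(1, c, 1, 1)
        return xn * g + b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n_vocab: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter((rng.standard_normal((n_vocab, d)) * 0.02))

    def forward(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, ids)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        return x.leaky_relu(self.alpha)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled state per parameter (no weight decay)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.99), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data.astype(np.float64) - self.lr * update).astype(p.data.dtype)

    def state_dict(self):
        return {"t": self.t, "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}
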