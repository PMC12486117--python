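"""Minimal tape-based reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the encoders and the calibrated loss need:
broadcast arithmetic, (batched) matmul, 2D convolution via im2col, common
elementwise nonlinearities, reductions, reshapes/transposes/concatenation
and slicing.  Everything is float64 and CPU-only, which keeps training
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ---- graph traversal ----

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # ---- arithmetic ----

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += -g

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1.0)

        out._backward = back
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def back(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += _unbroadcast(ga, self.data.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += _unbroadcast(gb, other.data.shape)

        out._backward = back
        return out

    # ---- elementwise ----

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * (self.data > 0)

        out._backward = back
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * s * (1.0 - s)

        out._backward = back
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * e

        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g / self.data

        out._backward = back
        return out

    def sqrt(self):
        return self**0.5

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * np.sign(self.data)

        out._backward = back
        return out

    def maximum(self, other):
        """Elementwise max; at ties the gradient flows to ``self``."""
        other = _as_tensor(other)
        out = Tensor(np.maximum(self.data, other.data), parents=(self, other))
        take_self = self.data >= other.data

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * take_self, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * ~take_self, other.data.shape)

        out._backward = back
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        inside = (self.data >= lo) & (self.data <= hi)

        def back(g):
            if self.requires_grad:
                self.grad += g * inside

        out._backward = back
        return out

    # ---- reductions / shape ----

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                self.grad += np.broadcast_to(g, self.data.shape)

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        out._backward = back
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self.grad += g.transpose(*inv)

        out._backward = back
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def back(g):
            if self.requires_grad:
                np.add.at(self.grad, key, g)

        out._backward = back
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.grad += piece

    out._backward = back
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# --------------------------------------------------------------------------
# 2D convolution (im2col)
# --------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    B, C, H, W = x.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    cols = np.empty((B, C, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(B, C * kh * kw, oh * ow)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    B, C, H, W = x_shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    cols = cols.reshape(B, C, kh, kw, oh, ow)
    x = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    return x


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """x: (B, C, H, W); w: (F, C, kh, kw); b: (F,). Zero padding."""
    F, C, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    B = xp.shape[0]
    cols = _im2col(xp, kh, kw, stride)  # (B, C*kh*kw, oh*ow)
    oh = (xp.shape[2] - kh) // stride + 1
    ow = (xp.shape[3] - kw) // stride + 1
    wm = w.data.reshape(F, -1)
    out_data = (wm @ cols).reshape(B, F, oh, ow) + b.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, w, b))

    def back(g):
        gm = g.reshape(B, F, oh * ow)
        if b.requires_grad:
            b.grad += g.sum(axis=(0, 2, 3))
        if w.requires_grad:
            w.grad += np.einsum("bfo,bko->fk", gm, cols).reshape(w.data.shape)
        if x.requires_grad:
            dcols = np.einsum("fk,bfo->bko", wm, gm)
            dxp = _col2im(dcols, xp.shape, kh, kw, stride)
            x.grad += dxp[:, :, pad : dxp.shape[2] - pad, pad : dxp.shape[3] - pad] if pad else dxp

    out._backward = back
    return out


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------


class Adam:
    """Standard Adam over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
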