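"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based tensor engine sufficient for the networks in this
package: dense layers, 2D convolutions (odd kernels, stride 1, 'same'
padding), 2x2 max pooling, nearest-neighbour upsampling, batched matrix
products, gathers, softmax heads, and elementwise arithmetic.  Everything
runs in float64 for numerical headroom; performance is adequate at the
problem sizes this package targets.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _as_array(x):
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph mechanics ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = _as_array(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # release the tape promptly: keep gradients only on leaves so each
        # step's intermediate buffers are freed without waiting for the GC
        for t in topo:
            if t._parents:
                t._backward = None
                t._parents = ()
                t.grad = None

    def _accumulate(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y ** 2))
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(src))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def gather(self, index: np.ndarray):
        """Index rows along axis 0 with a constant integer array."""
        index = np.asarray(index)
        out = Tensor(self.data[index], parents=(self,))

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index.reshape(-1), g.reshape(-1, *self.data.shape[1:]))
            self._accumulate(acc)

        out._backward = bwd
        return out

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- softmax heads -----------------------------------------------------
    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse
        out = Tensor(y, parents=(self,))

        def bwd(g):
            sm = np.exp(y)
            self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # -- image ops ---------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None):
        """'Same' 2D correlation, stride 1, odd square kernel.

        self: (N, C, H, W); weight: (O, C, k, k); bias: (O,).
        """
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, c2, kh, kw = w.shape
        if c != c2 or kh % 2 == 0 or kh != kw:
            raise ValueError("conv2d expects matching channels and odd square kernels")
        cols2, y = _corr2d(x, w)
        if bias is not None:
            y = y + bias.data[None, :, None, None]
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(y, parents=parents)

        def bwd(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(n * h * wd, o)
            if weight.requires_grad:
                gw = (cols2.T @ gmat).T.reshape(o, c, kh, kw)
                weight._accumulate(gw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                # dx is the same correlation applied to g with the kernel
                # flipped and its channel axes swapped
                wt = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
                _, gx = _corr2d(g, wt)
                self._accumulate(gx)

        out._backward = bwd
        return out

    def maxpool2d(self):
        """2x2 max pooling, stride 2; spatial dims must be even."""
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2d requires even spatial dimensions")
        blocks = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        y = blocks.max(axis=(3, 5))
        out = Tensor(y, parents=(self,))

        def bwd(g):
            mask = blocks == y[:, :, :, None, :, None]
            cnt = mask.sum(axis=(3, 5), keepdims=True)
            gx = mask * (g[:, :, :, None, :, None] / cnt)
            self._accumulate(gx.reshape(n, c, h, w))

        out._backward = bwd
        return out

    def upsample2d(self):
        """Nearest-neighbour 2x upsampling."""
        n, c, h, w = self.data.shape
        y = self.data.repeat(2, axis=2).repeat(2, axis=3)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            self._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        out._backward = bwd
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _corr2d(x: np.ndarray, w: np.ndarray):
    """'Same' correlation via im2col + one matmul; returns (cols, result)."""
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    p = kh // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * kh * kw)
    y = (cols2 @ w.reshape(o, -1).T).reshape(n, h, wd, o).transpose(0, 3, 1, 2)
    return cols2, y


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = bwd
    return out
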