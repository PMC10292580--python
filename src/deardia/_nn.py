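"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the embedding VAE and the co-elution CNN
need: dense affine layers, ReLU/sigmoid/exp/log nonlinearities, dropout,
channel concatenation, same-padded 2-D convolution (via im2col) and a
3x3 stride-1 max pool. Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "sigmoid", "exp", "log", "concat", "dropout",
           "conv2d_same", "maxpool3_same"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a backward closure on a dynamic tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            return (_unbroadcast(g, self.shape),
                    _unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = g @ b.T if b.ndim == 2 else np.outer(g, b)
            gb = a.T @ g if a.ndim == 2 else np.outer(a, g)
            return ga, gb
        out._backward = bwd
        return out

    def square(self):
        out = Tensor(self.data ** 2, parents=(self,))
        out._backward = lambda g: (2.0 * self.data * g,)
        return out

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), parents=(self,))

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            return (np.broadcast_to(np.expand_dims(g, axis), self.shape).copy(),)
        out._backward = bwd
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / n

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    # ---- backward pass ---------------------------------------------------

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() expects a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)
        visit(self)

        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._backward(t.grad)):
                if not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: (g * (x.data > 0.0),)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: (g * s * (1.0 - s),)
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(np.clip(x.data, -60, 60))
    out = Tensor(e, parents=(x,))
    out._backward = lambda g: (g * e,)
    return out


def log(x: Tensor, eps: float = 1e-12) -> Tensor:
    out = Tensor(np.log(x.data + eps), parents=(x,))
    out._backward = lambda g: (g / (x.data + eps),)
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))
    out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def conv2d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 2-D convolution.

    x: (N, C, H, W); w: (F, C, kh, kw) with odd kernel sizes; b: (F,).
    """
    N, C, H, W = x.shape
    F, C2, kh, kw = w.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> cols (N, H*W, C*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, H * W, C * kh * kw)
    wm = w.data.reshape(F, -1)
    y = cols @ wm.T + b.data  # (N, H*W, F)
    out = Tensor(y.transpose(0, 2, 1).reshape(N, F, H, W), parents=(x, w, b))

    def bwd(g):
        gmat = g.reshape(N, F, H * W).transpose(0, 2, 1)  # (N, H*W, F)
        gw = np.einsum("nif,nik->fk", gmat, cols).reshape(w.shape)
        gb = gmat.sum(axis=(0, 1))
        dcols = (gmat @ wm).reshape(N, H, W, C, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gxp[:, :, ph:ph + H, pw:pw + W], gw, gb
    out._backward = bwd
    return out


def maxpool3_same(x: Tensor) -> Tensor:
    """3x3 stride-1 max pool with same zero padding on (N, C, H, W)."""
    N, C, H, W = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)),
                constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    flat = win.reshape(N, C, H, W, 9)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bwd(g):
        gx = np.zeros((N, C, H + 2, W + 2))
        n, c, h, w = np.indices((N, C, H, W))
        np.add.at(gx, (n, c, h + arg // 3, w + arg % 3), g)
        return (gx[:, :, 1:1 + H, 1:1 + W],)
    out._backward = bwd
    return out
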