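"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the networks in this package:
windowed self-attention, MBConv, fusion modules, a convolutional
classification head, and an LSTM variant. Tensors wrap float64 numpy
arrays; every operation records a closure that accumulates gradients
into its parents. ``Tensor.backward()`` runs the tape in reverse
topological order.

Only the operations the package needs are implemented; shapes follow
the NCHW convention for images.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "depthwise_conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _acc(self, grad: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._acc(_unbroadcast(g, self.shape))
            other._acc(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._acc(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._acc(_unbroadcast(g * other.data, self.shape))
            other._acc(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._acc(_unbroadcast(g / other.data, self.shape))
            other._acc(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._acc(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._acc(_unbroadcast(ga, a.shape))
            other._acc(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._acc(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._acc(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._acc(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._acc(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            self._acc(g * (1.0 - t * t))

        return self._make(t, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._acc(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation of GELU
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._acc(g * d)

        return self._make(out_data, (self,), backward)

    def swish(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            self._acc(g * (s + self.data * s * (1.0 - s)))

        return self._make(out_data, (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._acc(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._acc(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max over one axis; gradient flows to the first maximal element."""
        am = np.expand_dims(self.data.argmax(axis=axis), axis)
        out_data = np.take_along_axis(self.data, am, axis=axis)
        if not keepdims:
            out_data = out_data.squeeze(axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, am, g, axis=axis)
            self._acc(full)

        return self._make(out_data, (self,), backward)

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Plain numpy max (used for softmax stabilisation; no gradient)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.max_detached(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape manipulation ---------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            self._acc(g.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._acc(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._acc(full)

        return self._make(self.data[idx], (self,), backward)

    def take(self, idx: np.ndarray) -> "Tensor":
        """Fancy gather with scatter-add gradient (for bias tables)."""
        return self[idx]

    def pad2d(self, pad: int):
        """Zero-pad the last two axes by `pad` on each side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]

        def backward(g):
            sl = tuple([slice(None)] * (self.ndim - 2) + [slice(pad, -pad)] * 2)
            self._acc(g[sl])

        return self._make(np.pad(self.data, width), (self,), backward)

    def roll(self, shift, axis):
        def backward(g):
            self._acc(np.roll(g, tuple(-s for s in shift), axis))

        return self._make(np.roll(self.data, shift, axis), (self,), backward)

    # -- pooling / resampling -------------------------------------------
    def avg_pool2d(self, k: int = 2):
        n, c, h, w = self.shape
        r = self.reshape(n, c, h // k, k, w // k, k)
        return r.mean(axis=(3, 5))

    def max_pool2d(self, k: int = 2):
        n, c, h, w = self.shape
        blocks = (self.data.reshape(n, c, h // k, k, w // k, k)
                  .transpose(0, 1, 2, 4, 3, 5)
                  .reshape(n, c, h // k, w // k, k * k))
        out_data = blocks.max(axis=4)
        am = blocks.argmax(axis=4)  # first maximal element wins ties

        def backward(g):
            gf = np.zeros_like(blocks)
            np.put_along_axis(gf, am[..., None], g[..., None], axis=4)
            gb = (gf.reshape(n, c, h // k, w // k, k, k)
                  .transpose(0, 1, 2, 4, 3, 5)
                  .reshape(n, c, h, w))
            self._acc(gb)

        return self._make(out_data, (self,), backward)

    def upsample_nearest(self, factor: int = 2):
        n, c, h, w = self.shape
        out_data = self.data.repeat(factor, axis=2).repeat(factor, axis=3)

        def backward(g):
            gb = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            self._acc(gb)

        return self._make(out_data, (self,), backward)

    # -- backward pass ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited = [], set()
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
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._acc(g[tuple(sl)])

        out._prev = tuple(tensors)
        out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    cols = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return cols[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)


def _col2im(gcols: np.ndarray, x_shape, kh, kw, stride):
    """Accumulate (N, C, Ho, Wo, kh, kw) gradients back onto the padded input."""
    n, c, hp, wp = x_shape
    ho, wo = gcols.shape[2], gcols.shape[3]
    dx = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                gcols[:, :, :, :, i, j]
            )
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, zero padding."""
    xp = x.pad2d(padding)
    n, c, hp, wp = xp.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight {ci}")
    cols = _im2col(xp.data, kh, kw, stride)  # (N, C, Ho, Wo, kh, kw)
    ho, wo = cols.shape[2], cols.shape[3]
    colmat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, c * kh * kw)
    out_data = (colmat @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    parents = (xp, w) if b is None else (xp, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        w._acc((gmat.T @ colmat).reshape(w.shape))
        if b is not None:
            b._acc(g.sum(axis=(0, 2, 3)))
        gcol = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        xp._acc(_col2im(gcol, (n, c, hp, wp), kh, kw, stride))

    out = Tensor(out_data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._prev = parents
        out._backward = backward
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise convolution: one k×k filter per channel. w: (C, kh, kw)."""
    xp = x.pad2d(padding)
    n, c, hp, wp = xp.shape
    cw, kh, kw = w.shape
    if cw != c:
        raise ValueError("depthwise filter count must equal channel count")
    cols = _im2col(xp.data, kh, kw, stride)
    out_data = np.einsum("nchwkl,ckl->nchw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    parents = (xp, w) if b is None else (xp, w, b)

    def backward(g):
        w._acc(np.einsum("nchwkl,nchw->ckl", cols, g, optimize=True))
        if b is not None:
            b._acc(g.sum(axis=(0, 2, 3)))
        gcol = g[:, :, :, :, None, None] * w.data[None, :, None, None, :, :]
        xp._acc(_col2im(gcol, (n, c, hp, wp), kh, kw, stride))

    out = Tensor(out_data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._prev = parents
        out._backward = backward
    return out
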