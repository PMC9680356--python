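"""Compact reverse-mode autodiff on numpy arrays.

Only the operations the package needs are implemented: broadcast
arithmetic, matmul, exp/log/pow, relu, reductions, reshape/transpose,
2-D convolution (im2col + BLAS) and stop-gradient.  Gradients are
accumulated on ``Tensor.grad`` by :meth:`Tensor.backward`, which walks a
topological ordering of the recorded graph.

Float handling: integer/float64 inputs keep their precision (loss-level
checks run in float64); network parameters are float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d"]


def _as_float(data):
    # bare python numbers become float32 0-d arrays so that wrapping a
    # scalar constant never upcasts a float32 network graph to float64
    # (float64 inputs keep float64 end to end)
    if isinstance(data, (int, float)) and not isinstance(data, np.generic):
        return np.asarray(data, dtype=np.float32)
    a = np.asarray(data)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


def _coerce(other, dtype):
    """Wrap a binary-op operand; python numbers adopt ``dtype`` so scalar
    constants never change the precision of the graph they enter."""
    if isinstance(other, Tensor):
        return other
    if isinstance(other, (int, float)):
        return Tensor(np.asarray(other, dtype=dtype))
    return Tensor(other)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] > 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in out._parents)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- convenience ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _coerce(other, self.data.dtype)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-_coerce(other, self.data.dtype))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = _coerce(other, self.data.dtype)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _coerce(other, self.data.dtype) ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def back(g):
            a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._make(a.data ** e, (a,), back)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), back)

    # -- elementwise ----------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def back(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), back)

    def log(self):
        a = self

        def back(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), back)

    def relu(self):
        a = self
        mask = a.data > 0

        def back(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), back)

    def clamp_min(self, lo: float):
        a = self
        mask = a.data >= lo

        def back(g):
            a._accumulate(g * mask)

        return Tensor._make(np.maximum(a.data, lo), (a,), back)

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else axis
                g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(out_data, (a,), back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def back(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), back)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def back(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), back)


# -- 2-D convolution ----------------------------------------------------

def _col2im(dcols, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[:, :, i, j]
    if pad:
        dxp = dxp[:, :, pad:pad + h, pad:pad + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with (F, C, kh, kw) filters."""
    xd = x.data
    n, c, h, w = xd.shape
    f, cin, kh, kw = weight.data.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {c} channels, filters expect {cin}")
    xp = np.pad(xd, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) if padding else xd
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * kh * kw, oh * ow)
    w2 = weight.data.reshape(f, -1)
    out = np.matmul(w2, cols)
    if bias is not None:
        out = out + bias.data.reshape(1, f, 1)
    out = out.reshape(n, f, oh, ow)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def back(g):
        g2 = g.reshape(n, f, oh * ow)
        if weight.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)
            x._accumulate(_col2im(dcols, xd.shape, kh, kw, stride, padding))

    return Tensor._make(out, parents, back)
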