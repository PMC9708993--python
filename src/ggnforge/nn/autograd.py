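"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the networks in this package need:
broadcasting arithmetic, log/exp/sigmoid/relu, matmul, reductions, reshape,
slicing, and strided 2-D convolution (via im2col).  Gradients are
accumulated by a topological-order backward sweep from a scalar loss.
All tensors are float32; this keeps desk-scale training fast on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req,
                     _prev=tuple(p for p in parents if p.requires_grad) if req else ())
        if req:
            out._backward = backward
        return out

    def _acc(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._acc(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._acc(_unbroadcast(g, b.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._acc(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._acc(_unbroadcast(g * a.data, b.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        def backward(g, a=self):
            if a.requires_grad:
                a._acc(g * exponent * a.data ** (exponent - 1.0))
        return self._make(self.data ** exponent, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._acc(g / a.data)
        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._acc(g * o)
        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._acc(g * o * (1.0 - o))
        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._acc(g * m)
        return self._make(self.data * mask, (self,), backward)

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._acc(g @ b.data.T)
            if b.requires_grad:
                b._acc(a.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._acc(np.broadcast_to(g, a.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._acc(np.broadcast_to(gg, a.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        old = self.shape
        def backward(g, a=self, o=old):
            if a.requires_grad:
                a._acc(g.reshape(o))
        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, i=idx):
            if a.requires_grad:
                full = np.zeros(a.shape, dtype=np.float32)
                full[i] = g
                a._acc(full)
        return self._make(self.data[idx], (self,), backward)

    # -- backward sweep ----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
    dc = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                dc[:, :, :, :, i, j]
            )
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) of NCHW input with OIkk weights."""
    n = x.data.shape[0]
    o, c_in, k, _ = weight.data.shape
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(o, -1)
    out_data = cols @ wmat.T  # (n, ho*wo, o)
    out_data = out_data.transpose(0, 2, 1).reshape(n, o, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, o, 1, 1)

    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(g, x=x, weight=weight, bias=bias, cols=cols,
                 wmat=wmat, ho=ho, wo=wo, k=k, stride=stride, pad=pad, o=o):
        gmat = g.reshape(g.shape[0], o, ho * wo).transpose(0, 2, 1)  # (n, L, o)
        if weight.requires_grad:
            dw = np.einsum("nlo,nlc->oc", gmat, cols, optimize=True)
            weight._acc(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._acc(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = gmat @ wmat  # (n, L, c*k*k)
            x._acc(_col2im(dcols, x.data.shape, k, stride, pad, ho, wo))

    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, requires_grad=req,
                 _prev=tuple(p for p in parents if p.requires_grad) if req else ())
    if req:
        out._backward = backward
    return out
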