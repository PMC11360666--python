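"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the whole detector: a tape-based
``Tensor`` wrapping a float32 ndarray, a small set of differentiable
primitives (elementwise algebra, matmul, shape surgery, reductions,
softmax/activations), and a ``no_grad`` mode for inference where no graph
is recorded. Spatial primitives (convolution, pooling, normalization,
the state-space scan) live in :mod:`ecgdet.nnops`.

Only what the network needs is implemented; broadcasting follows numpy
semantics and gradients of broadcast operands are reduced back to the
operand shape.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from . import flops

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype == np.float64:
        return a  # double precision is preserved (oracle-grade paths)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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
    """A float32 array plus (optionally) a node in the backward tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = ()
        self._backward = None

    # -- construction of op results -------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior graph state as we go
                node._backward = None
                node._parents = ()

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise ---------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def sub(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(unbroadcast(-g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def mul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def div(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def power(a, p: float):
    a = astensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1))

    return Tensor._result(out_data, (a,), backward)


def exp(a):
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor._result(out_data, (a,), backward)


def log(a):
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor._result(out_data, (a,), backward)


def sqrt(a):
    a = astensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

    return Tensor._result(out_data, (a,), backward)


def sigmoid(a):
    a = astensor(a)
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (a,), backward)


def silu(a):
    """x * sigmoid(x) — the default activation throughout the network."""
    a = astensor(a)
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)
    out_data = x * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (s * (1.0 + x * (1.0 - s))))

    return Tensor._result(out_data, (a,), backward)


def atan(a):
    a = astensor(a)
    out_data = np.arctan(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / (1.0 + a.data * a.data))

    return Tensor._result(out_data, (a,), backward)


def clip(a, lo, hi):
    a = astensor(a)
    out_data = np.clip(a.data, lo, hi)

    def backward(g):
        if a.requires_grad:
            mask = ((a.data >= lo) & (a.data <= hi)).astype(np.float32)
            a._accumulate(g * mask)

    return Tensor._result(out_data, (a,), backward)


def maximum(a, b):
    a, b = astensor(a), astensor(b)
    out_data = np.maximum(a.data, b.data)

    def backward(g):
        amask = (a.data >= b.data).astype(np.float32)
        if a.requires_grad:
            a._accumulate(unbroadcast(g * amask, a.data.shape))
        if b.requires_grad:
            b._accumulate(unbroadcast(g * (1.0 - amask), b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


# -- linear algebra ------------------------------------------------------

def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = np.matmul(a.data, b.data)
    if flops.counting():
        flops.add_macs(out_data.size * a.data.shape[-1])

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(unbroadcast(gb, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


# -- shape surgery -------------------------------------------------------

def reshape(a, *shape):
    a = astensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out_data = a.data.reshape(shape)
    in_shape = a.data.shape

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(in_shape))

    return Tensor._result(out_data, (a,), backward)


def transpose(a, axes=None):
    a = astensor(a)
    out_data = np.transpose(a.data, axes)
    if axes is None:
        inv = None
    else:
        inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    return Tensor._result(out_data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._result(out_data, tuple(tensors), backward)


def getitem(a, idx):
    a = astensor(a)
    out_data = a.data[idx]
    in_shape = a.data.shape

    def backward(g):
        if a.requires_grad:
            ga = np.zeros(in_shape, dtype=np.float32)
            np.add.at(ga, idx, g)
            a._accumulate(ga)

    return Tensor._result(out_data, (a,), backward)


def split(a, sections, axis=0):
    """Split into chunks of the listed sizes along `axis`."""
    a = astensor(a)
    offsets = np.cumsum([0] + list(sections))
    if offsets[-1] != a.data.shape[axis]:
        raise ValueError(
            f"split sections {sections} do not sum to axis size {a.data.shape[axis]}")
    outs = []
    for lo, hi in zip(offsets[:-1], offsets[1:]):
        idx = [slice(None)] * a.data.ndim
        idx[axis] = slice(int(lo), int(hi))
        outs.append(getitem(a, tuple(idx)))
    return outs


# -- reductions ----------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    in_shape = a.data.shape

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accumulate(np.broadcast_to(g, in_shape).astype(np.float32))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, in_shape).astype(np.float32))

    return Tensor._result(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = astensor(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.data.shape[ax] for ax in axis]))
    else:
        n = a.data.shape[axis]
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def softmax(a, axis=-1):
    a = astensor(a)
    x = a.data
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return Tensor._result(out_data, (a,), backward)


def bce_with_logits(logits, targets):
    """Numerically stable elementwise binary cross-entropy on logits.

    targets is a plain ndarray (no gradient flows into it).
    """
    logits = astensor(logits)
    x = logits.data
    t = np.asarray(targets, dtype=np.float32)
    out_data = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        if logits.requires_grad:
            s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                         np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
            logits._accumulate(g * (s - t))

    return Tensor._result(out_data, (logits,), backward)


def where_const(cond, a, b):
    """Select between two tensors with a constant boolean mask."""
    cond = np.asarray(cond, dtype=bool)
    a, b = astensor(a), astensor(b)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(unbroadcast(g * cond, a.data.shape))
        if b.requires_grad:
            b._accumulate(unbroadcast(g * (~cond), b.data.shape))

    return Tensor._result(out_data, (a, b), backward)
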