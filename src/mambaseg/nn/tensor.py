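"""A small reverse-mode automatic-differentiation engine on numpy arrays.

The segmentation network in this package is trained on CPU; the graph is a
plain DAG of :class:`Tensor` nodes, each holding a numpy array and a backward
closure.  Only the primitives the architecture needs are implemented.  All
floating data is float32 unless a caller passes float64 explicitly.
"""

from __future__ import annotations

import contextlib
from typing import Iterable

import numpy as np

_GRAD_ENABLED = True


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


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, dtype=np.float32):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        """Create an op output; attaches the graph only when grads are on."""
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = track
        out._backward = backward if track else None
        out._prev = tuple(p for p in parents if p.requires_grad) if track else ()
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort (deep nets overflow recursion)
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node._prev:
                    node._backward = None  # release closures/buffers eagerly

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._result(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._result(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other, self.data.dtype) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accum(g * p * np.power(a.data, p - 1))

        return Tensor._result(np.power(a.data, p), (a,), bw)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return Tensor._result(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._result(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._result(s, (a,), bw)

    def silu(self):
        a = self
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-a.data))
        out_data = a.data * s

        def bw(g):
            a._accum(g * (s + a.data * s * (1.0 - s)))

        return Tensor._result(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._result(a.data * mask, (a,), bw)

    def softplus(self):
        a = self
        out_data = np.logaddexp(0.0, a.data).astype(a.data.dtype)
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * s)

        return Tensor._result(out_data, (a,), bw)

    def abs(self):
        """|x| with sign subgradient (0 at exactly 0)."""
        a = self
        sign = np.sign(a.data)

        def bw(g):
            a._accum(g * sign)

        return Tensor._result(np.abs(a.data), (a,), bw)

    def max(self, axis: int, keepdims: bool = False):
        """Max reduction; gradient routes to the (first) argmax elements."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data)
        # route to a single argmax per reduced slice for a well-defined subgradient
        first = np.cumsum(mask, axis=axis) == 1
        mask = mask & first

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(g * mask)

        return Tensor._result(out_data if keepdims else out_data.squeeze(axis), (a,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside [lo, hi]."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def bw(g):
            a._accum(g * mask)

        return Tensor._result(np.clip(a.data, lo, hi), (a,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._result(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Raw max of the data, outside the graph (for stable softmax)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            a._accum(g.reshape(old))

        return Tensor._result(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return Tensor._result(np.ascontiguousarray(a.data.transpose(axes)), (a,), bw)

    def flip(self, axis):
        a = self
        sl = tuple(
            slice(None, None, -1) if ax in (axis if isinstance(axis, tuple) else (axis,)) else slice(None)
            for ax in range(a.data.ndim)
        )

        def bw(g):
            a._accum(g[sl])

        return Tensor._result(np.ascontiguousarray(a.data[sl]), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._result(a.data[idx], (a,), bw)

    def matmul(self, other: "Tensor"):
        a, b = self, _as_tensor(other, self.data.dtype)

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._result(np.matmul(a.data, b.data), (a, b), bw)

    __matmul__ = matmul


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = tuple(
                    slice(lo, hi) if ax == (axis % g.ndim) else slice(None) for ax in range(g.ndim)
                )
                t._accum(g[sl])

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shp = list(t.shape)
        shp.insert(axis if axis >= 0 else t.ndim + axis + 1, 1)
        expanded.append(t.reshape(*shp))
    return concat(expanded, axis=axis)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - Tensor(x.max_detached(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int) -> Tensor:
    return log_softmax(x, axis).exp()
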