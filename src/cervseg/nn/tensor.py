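"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and remembers how it was produced;
calling :meth:`Tensor.backward` on a scalar output walks the recorded graph
in reverse topological order and accumulates gradients into every ancestor.
Only the operations the segmentation network needs are provided — this is
infrastructure, not a general framework.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(data):
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward_fn = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
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
        _accumulate(self, np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, -_ensure(other))

    def __rsub__(self, other):
        return add(_ensure(other), -self)

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, 1.0 / float(other))
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_ensure(other), self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g  # views are safe: accumulation below never mutates in place
    else:
        t.grad = t.grad + g


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(isinstance(p, Tensor) for p in parents):
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward_fn = backward_fn
        out.requires_grad = any(p.requires_grad for p in out._parents)
    return out


# -- elementwise ops -------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)

    def bwd(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bwd)


def div(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)

    def bwd(g):
        _accumulate(a, _unbroadcast(g / b.data, a.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _make(a.data / b.data, (a, b), bwd)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    a = _ensure(a)

    def bwd(g):
        _accumulate(a, g * s)

    return _make(a.data * s, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    a = _ensure(a)
    mask = a.data > 0

    def bwd(g):
        _accumulate(a, g * mask)

    return _make(a.data * mask, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    a = _ensure(a)
    y = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        _accumulate(a, g * y * (1.0 - y))

    return _make(y, (a,), bwd)


def log(a: Tensor) -> Tensor:
    a = _ensure(a)

    def bwd(g):
        _accumulate(a, g / a.data)

    return _make(np.log(a.data), (a,), bwd)


# -- reductions / shape ----------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)

    def bwd(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g, a.shape).astype(a.data.dtype))
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            _accumulate(a, np.broadcast_to(gg, a.shape).astype(a.data.dtype))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul_scalar(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    a = _ensure(a)
    old = a.shape

    def bwd(g):
        _accumulate(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def broadcast_spatial(a: Tensor, h: int, w: int) -> Tensor:
    """Broadcast an (N, C, 1, 1) map to (N, C, h, w)."""
    a = _ensure(a)

    def bwd(g):
        _accumulate(a, g.sum(axis=(2, 3), keepdims=True))

    return _make(np.broadcast_to(a.data, a.shape[:2] + (h, w)).copy(), (a,), bwd)


def constant(data) -> Tensor:
    """A graph leaf that never receives gradient (stop-gradient wrapper)."""
    return Tensor(np.asarray(data))
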