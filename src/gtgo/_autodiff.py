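"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs: broadcast arithmetic,
dense and sparse-times-dense matrix products, ReLU, sigmoid, log, sqrt,
clipping, row gather, axis sums and column concatenation.  Gradients are
accumulated by a topological-order backward sweep.  Everything is float64.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp

__all__ = ["Tensor", "constant", "concat", "relu", "spmm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def detach(self) -> "Tensor":
        return Tensor(self.value.copy())

    def _make(self, value, parents, backward) -> "Tensor":
        out = Tensor(value)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.value + b.value, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-a.value, (a,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.value, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.value, b.shape))

        return self._make(a.value * b.value, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.value, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.value / (b.value**2), b.shape))

        return self._make(a.value / b.value, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.value.T)
            if b.requires_grad:
                b._accum(a.value.T @ g)

        return self._make(a.value @ b.value, (a, b), backward)

    def t(self) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g.T)

        return self._make(a.value.T, (a,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.full(a.shape, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.value.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.value.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinear ------------------------------------------------
    def sqrt(self) -> "Tensor":
        a = self
        out_val = np.sqrt(a.value)

        def backward(g):
            if a.requires_grad:
                a._accum(g * 0.5 / out_val)

        return self._make(out_val, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.value)

        return self._make(np.log(a.value), (a,), backward)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-a.value))

        def backward(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return self._make(s, (a,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        a = self
        mask = (a.value >= lo) & (a.value <= hi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return self._make(np.clip(a.value, lo, hi), (a,), backward)

    def take_rows(self, idx) -> "Tensor":
        a = self
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            if a.requires_grad:
                full = np.zeros(a.shape)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._make(a.value[idx], (a,), backward)

    # -- backward sweep -------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def relu(x: Tensor) -> Tensor:
    mask = x.value > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return x._make(x.value * mask, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    vals = [t.value for t in tensors]
    sizes = [v.shape[axis] for v in vals]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(np.concatenate(vals, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def spmm(mat: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a dense tensor."""
    mat = sp.csr_matrix(mat)
    mat_t = mat.T.tocsr()

    def backward(g):
        if x.requires_grad:
            x._accum(mat_t @ g)

    out = Tensor(mat @ x.value)
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)
        out._backward = backward
    return out
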