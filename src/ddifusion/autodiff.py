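"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (two 3-layer GCN encoders, a per-view
attention map and a feed-forward head), so rather than depending on a deep
learning framework the package carries its own compact tape-based autodiff:
a :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the primitives the model needs are implemented.

Gradient correctness is pinned by finite-difference checks in the test
suite; every composite layer (softmax, batch norm, losses) is built from
these primitives so it inherits exact gradients.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "neg",
    "sub",
    "power",
    "log",
    "exp",
    "relu",
    "leaky_relu",
    "sigmoid",
    "reduce_sum",
    "concat_cols",
    "gather_rows",
    "slice_cols",
    "clip",
    "softmax_rows",
    "l2_normalize_rows",
]


class Tensor:
    """A node in the autodiff graph.

    Parameters are created with ``requires_grad=True``; constants (inputs,
    masks) with ``False``.  Gradients accumulate into ``.grad`` on
    :meth:`backward`.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value: np.ndarray | float,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.value)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Operator sugar (used sparingly in model code).
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return sub(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value + b.value

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value * b.value

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.value, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=bw)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        if a.requires_grad:
            a._accumulate(-g)

    return Tensor(-a.value, parents=(a,), backward=bw)


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value @ b.value

    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.value.T)
        if b.requires_grad:
            b._accumulate(a.value.T @ g)

    return Tensor(out_val, parents=(a, b), backward=bw)


def power(a, exponent: float) -> Tensor:
    """Elementwise ``a ** exponent`` for a constant exponent."""
    a = as_tensor(a)
    out_val = a.value**exponent

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.value ** (exponent - 1.0))

    return Tensor(out_val, parents=(a,), backward=bw)


def log(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g / a.value)

    return Tensor(np.log(a.value), parents=(a,), backward=bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_val = np.exp(a.value)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * out_val)

    return Tensor(out_val, parents=(a,), backward=bw)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(a.value * mask, parents=(a,), backward=bw)


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    slope = np.where(a.value > 0, 1.0, negative_slope)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * slope)

    return Tensor(a.value * slope, parents=(a,), backward=bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_val = 1.0 / (1.0 + np.exp(-a.value))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * out_val * (1.0 - out_val))

    return Tensor(out_val, parents=(a,), backward=bw)


def reduce_sum(a, axis: int | None = None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_val = a.value.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.value.shape))

    return Tensor(out_val, parents=(a,), backward=bw)


def concat_cols(parts: Sequence) -> Tensor:
    """Concatenate 2-D tensors along axis 1."""
    parts = [as_tensor(p) for p in parts]
    widths = [p.value.shape[1] for p in parts]
    offsets = np.concatenate([[0], np.cumsum(widths)])
    out_val = np.concatenate([p.value for p in parts], axis=1)

    def bw(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                p._accumulate(g[:, lo:hi])

    return Tensor(out_val, parents=tuple(parts), backward=bw)


def gather_rows(a, index: np.ndarray) -> Tensor:
    """Select rows ``a[index]``; backward scatter-adds."""
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.intp)

    def bw(g):
        if a.requires_grad:
            acc = np.zeros_like(a.value)
            np.add.at(acc, index, g)
            a._accumulate(acc)

    return Tensor(a.value[index], parents=(a,), backward=bw)


def slice_cols(a, lo: int, hi: int) -> Tensor:
    """Column slice ``a[:, lo:hi]`` of a 2-D tensor."""
    a = as_tensor(a)

    def bw(g):
        if a.requires_grad:
            acc = np.zeros_like(a.value)
            acc[:, lo:hi] = g
            a._accumulate(acc)

    return Tensor(a.value[:, lo:hi], parents=(a,), backward=bw)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the bounds."""
    a = as_tensor(a)
    mask = (a.value > lo) & (a.value < hi)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(np.clip(a.value, lo, hi), parents=(a,), backward=bw)


def softmax_rows(a) -> Tensor:
    """Numerically stable softmax along axis 1, composed from primitives."""
    a = as_tensor(a)
    shift = sub(a, a.value.max(axis=1, keepdims=True))  # constant shift
    e = exp(shift)
    total = reduce_sum(e, axis=1, keepdims=True)
    return mul(e, power(total, -1.0))


def l2_normalize_rows(a, eps: float = 1e-12) -> Tensor:
    """Scale each row of ``a`` to unit Euclidean norm."""
    a = as_tensor(a)
    sq = reduce_sum(mul(a, a), axis=1, keepdims=True)
    return mul(a, power(add(sq, eps), -0.5))
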