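"""Minimal reverse-mode automatic differentiation over numpy arrays.

The message-passing network needs only a small, fixed vocabulary of
differentiable operations (dense layers, gather/scatter over edge lists,
elementwise products and a smooth activation).  Rather than pull in a deep
learning framework for that, this module provides a tape-based autodiff
engine: each operation returns a :class:`Var` holding the forward value and
a vector-Jacobian-product closure; :func:`backward` walks the tape in
reverse topological order.

Gradients are verified against central finite differences in the test
suite.  All arrays are plain ``numpy.ndarray``; dtype is whatever the
caller supplies (float32 for training speed, float64 for inference).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Var",
    "add",
    "matmul",
    "matmul_concat",
    "mul",
    "concat",
    "take_rows",
    "segment_sum",
    "ssp",
    "mean_abs",
    "mean_sq",
    "backward",
]

_LN2 = float(np.log(2.0))


class Var:
    """A node on the autodiff tape.

    Parameters
    ----------
    value : ndarray
        Forward value.
    parents : tuple of Var
        Inputs this node was computed from (empty for leaves).
    vjp : callable or None
        Maps the gradient w.r.t. this node to a tuple of gradients
        w.r.t. each parent.  ``None`` marks a leaf or constant.
    """

    __slots__ = ("value", "grad", "parents", "vjp")

    def __init__(self, value, parents=(), vjp=None):
        self.value = np.asarray(value)
        self.grad = None
        self.parents = parents
        self.vjp = vjp

    @property
    def shape(self):
        return self.value.shape


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Var, b: Var) -> Var:
    def vjp(g):
        return _unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)

    return Var(a.value + b.value, (a, b), vjp)


def mul(a: Var, b: Var) -> Var:
    def vjp(g):
        return (
            _unbroadcast(g * b.value, a.value.shape),
            _unbroadcast(g * a.value, b.value.shape),
        )

    return Var(a.value * b.value, (a, b), vjp)


def matmul(a: Var, b: Var) -> Var:
    def vjp(g):
        return g @ b.value.T, a.value.T @ g

    return Var(a.value @ b.value, (a, b), vjp)


def concat(vars_: list[Var], axis: int = 1) -> Var:
    sizes = [v.value.shape[axis] for v in vars_]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Var(np.concatenate([v.value for v in vars_], axis=axis), tuple(vars_), vjp)


def _scatter_matrix(idx: np.ndarray, n_rows: int, dtype) -> sp.csr_matrix:
    """Sparse (n_rows x len(idx)) accumulator: S @ x == scatter-add of x."""
    m = len(idx)
    return sp.csr_matrix(
        (np.ones(m, dtype=dtype), (idx, np.arange(m))), shape=(n_rows, m)
    )


def take_rows(a: Var, idx: np.ndarray) -> Var:
    """Row gather ``a[idx]``; the backward pass scatter-adds."""

    def vjp(g):
        if g.ndim == 2:
            return (_scatter_matrix(idx, a.value.shape[0], g.dtype) @ g,)
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return (out,)

    return Var(a.value[idx], (a,), vjp)


def segment_sum(a: Var, seg: np.ndarray, n_segments: int) -> Var:
    """Sum rows of ``a`` into ``n_segments`` buckets given by ``seg``."""
    if a.value.ndim == 2:
        out = _scatter_matrix(seg, n_segments, a.value.dtype) @ a.value
    else:
        out = np.zeros((n_segments,) + a.value.shape[1:], dtype=a.value.dtype)
        np.add.at(out, seg, a.value)

    def vjp(g):
        return (g[seg],)

    return Var(out, (a,), vjp)


def ssp(a: Var) -> Var:
    """Shifted softplus ln(0.5 e^x + 0.5); smooth, ssp(0) = 0."""
    x = a.value
    ex = np.exp(-np.abs(x))  # overflow-safe softplus building block
    val = (np.maximum(x, 0) + np.log1p(ex) - _LN2).astype(x.dtype)

    def vjp(g):
        # softplus' = sigmoid(x) = 1 - e^{-softplus(x)} = 1 - 0.5 e^{-val}
        sig = 1.0 - 0.5 * np.exp(-val)
        return (g * sig,)

    return Var(val, (a,), vjp)


def matmul_concat(parts: list[Var], w: Var) -> Var:
    """``concat(parts, axis=1) @ w`` without materializing the concat."""
    sizes = [p.value.shape[1] for p in parts]
    offs = np.cumsum([0] + sizes)
    out = parts[0].value @ w.value[offs[0] : offs[1]]
    for k in range(1, len(parts)):
        out += parts[k].value @ w.value[offs[k] : offs[k + 1]]

    def vjp(g):
        gw = np.empty_like(w.value)
        grads = []
        for k, p in enumerate(parts):
            blk = slice(offs[k], offs[k + 1])
            grads.append(g @ w.value[blk].T)
            gw[blk] = p.value.T @ g
        return (*grads, gw)

    return Var(out, (*parts, w), vjp)


def mean_abs(a: Var, target: np.ndarray) -> Var:
    """Mean absolute deviation of ``a`` from a constant target."""
    diff = a.value - target
    n = max(diff.size, 1)

    def vjp(g):
        return (g * np.sign(diff) / n,)

    return Var(np.abs(diff).mean(), (a,), vjp)


def mean_sq(a: Var, target: np.ndarray) -> Var:
    diff = a.value - target
    n = max(diff.size, 1)

    def vjp(g):
        return (g * 2.0 * diff / n,)

    return Var((diff**2).mean(), (a,), vjp)


def backward(root: Var) -> None:
    """Populate ``.grad`` on every tape node reachable from ``root``."""
    order: list[Var] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))

    for node in order:
        node.grad = None
    root.grad = np.ones_like(root.value)
    for node in reversed(order):
        if node.vjp is None or node.grad is None:
            continue
        grads = node.vjp(node.grad)
        for parent, g in zip(node.parents, grads):
            if g is None:
                continue
            # no in-place accumulation: vjp outputs may alias each other
            parent.grad = g if parent.grad is None else parent.grad + g
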