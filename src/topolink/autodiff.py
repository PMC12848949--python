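"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the graph
encoders and losses need: broadcasting arithmetic, matmul, reductions,
row gather/scatter (the sparse message-passing primitives), segment
reductions, concatenation and the usual pointwise nonlinearities.
All computation is float64.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the tape and runs each node's backward closure.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "rows",
    "scatter_sum",
    "segment_max",
    "segment_min",
    "take_per_row",
    "maximum",
    "minimum",
    "leaky_relu",
    "elu",
    "sigmoid",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        if parents and backward is not None:
            self.requires_grad = any(p.requires_grad for p in parents)
        else:
            self.requires_grad = requires_grad

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode differentiation from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        a, b = self, _as_tensor(other)
        out_data = a.data + b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, parents=(a, b), backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor(-a.data, parents=(a,), backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        a, b = self, _as_tensor(other)
        out_data = a.data * b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(out_data, parents=(a, b), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        a, b = self, _as_tensor(other)
        out_data = a.data / b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor(out_data, parents=(a, b), backward=bw)

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        a = self
        out_data = a.data ** exponent

        def bw(g):
            if a.requires_grad:
                a._accum(g * exponent * a.data ** (exponent - 1))

        return Tensor(out_data, parents=(a,), backward=bw)

    def __matmul__(self, other) -> "Tensor":
        a, b = self, _as_tensor(other)
        out_data = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor(out_data, parents=(a, b), backward=bw)

    @property
    def T(self) -> "Tensor":
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(g.T)

        return Tensor(a.data.T, parents=(a,), backward=bw)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor(out_data, parents=(a,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------------- pointwise
    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor(out_data, parents=(a,), backward=bw)

    def log(self) -> "Tensor":
        a = self
        out_data = np.log(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor(out_data, parents=(a,), backward=bw)

    def sqrt(self) -> "Tensor":
        return self ** 0.5


# ------------------------------------------------------------------ functions

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows ``a[idx]``; the adjoint is a scatter-add."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            a._accum(ga)

    return Tensor(out_data, parents=(a,), backward=bw)


def scatter_sum(src: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    """out[s] = sum of src rows with idx == s; the adjoint is a gather."""
    idx = np.asarray(idx, dtype=np.intp)
    shape = (num_segments,) + src.data.shape[1:]
    out_data = np.zeros(shape, dtype=np.float64)
    np.add.at(out_data, idx, src.data)

    def bw(g):
        if src.requires_grad:
            src._accum(g[idx])

    return Tensor(out_data, parents=(src,), backward=bw)


def _segment_extreme(src: Tensor, idx: np.ndarray, num_segments: int,
                     mode: str) -> Tensor:
    """Per-segment max/min over rows; empty segments yield 0.

    The gradient flows to the winning row per (segment, column); ties are
    broken toward the earliest row, matching numpy's first-occurrence rule.
    """
    idx = np.asarray(idx, dtype=np.intp)
    n_cols = src.data.shape[1]
    out_data = np.zeros((num_segments, n_cols), dtype=np.float64)
    winner = np.full((num_segments, n_cols), -1, dtype=np.intp)
    fill = -np.inf if mode == "max" else np.inf
    best = np.full((num_segments, n_cols), fill, dtype=np.float64)
    better = np.greater if mode == "max" else np.less
    for r in range(src.data.shape[0]):
        s = idx[r]
        improved = better(src.data[r], best[s])
        best[s, improved] = src.data[r, improved]
        winner[s, improved] = r
    filled = winner >= 0
    out_data[filled] = best[filled]

    def bw(g):
        if not src.requires_grad:
            return
        gs = np.zeros_like(src.data)
        seg_i, col_i = np.nonzero(filled)
        gs[winner[seg_i, col_i], col_i] += g[seg_i, col_i]
        src._accum(gs)

    return Tensor(out_data, parents=(src,), backward=bw)


def segment_max(src: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    return _segment_extreme(src, idx, num_segments, "max")


def segment_min(src: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    return _segment_extreme(src, idx, num_segments, "min")


def take_per_row(a: Tensor, cols: np.ndarray) -> Tensor:
    """out[i] = a[i, cols[i]]."""
    cols = np.asarray(cols, dtype=np.intp)
    r = np.arange(a.data.shape[0])
    out_data = a.data[r, cols]

    def bw(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, (r, cols), g)
            a._accum(ga)

    return Tensor(out_data, parents=(a,), backward=bw)


def maximum(a: Tensor, b) -> Tensor:
    """Elementwise max; on ties the gradient goes to ``a``."""
    a, b = _as_tensor(a), _as_tensor(b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def minimum(a: Tensor, b) -> Tensor:
    """Elementwise min; on ties the gradient goes to ``a``."""
    a, b = _as_tensor(a), _as_tensor(b)
    take_a = a.data <= b.data
    out_data = np.where(take_a, a.data, b.data)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def leaky_relu(a: Tensor, negative_slope: float = 0.2) -> Tensor:
    pos = a.data > 0
    out_data = np.where(pos, a.data, negative_slope * a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * np.where(pos, 1.0, negative_slope))

    return Tensor(out_data, parents=(a,), backward=bw)


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    pos = a.data > 0
    neg_val = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    out_data = np.where(pos, a.data, neg_val)

    def bw(g):
        if a.requires_grad:
            a._accum(g * np.where(pos, 1.0, neg_val + alpha))

    return Tensor(out_data, parents=(a,), backward=bw)


def sigmoid(a: Tensor) -> Tensor:
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=bw)
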