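"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small and CPU-bound, and the deployment
environment provides no deep-learning framework, so the network runs on
a compact tape-based autodiff engine: a :class:`Tensor` wraps a float64
ndarray and records a backward closure per operation. Only the
operations the architecture needs are implemented. Gradients are exact
(verified against finite differences in the test suite).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "set_default_dtype",
    "get_default_dtype",
    "matmul",
    "swapaxes",
    "reshape",
    "concat",
    "softmax",
    "elu",
    "leaky_relu",
    "sigmoid",
    "max_along",
]


_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the float dtype for new tensors (float64 default).

    float32 roughly halves training time on one CPU; float64 is kept as
    the default so finite-difference gradient checks stay exact.
    """
    global _DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.float32, np.float64):
        raise TypeError(f"unsupported dtype {dtype}")
    _DTYPE = dtype.type


def get_default_dtype():
    return _DTYPE


@contextmanager
def default_dtype(dtype):
    """Temporarily switch the default float dtype."""
    previous = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(previous)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ---- graph -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this tensor (seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data
        rg = self.requires_grad or other.requires_grad
        if not rg:
            return Tensor(out_data)

        def backward(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, True, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data
        rg = self.requires_grad or other.requires_grad
        if not rg:
            return Tensor(out_data)

        def backward(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, True, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (requires_grad always on)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = a.data @ b.data
    rg = a.requires_grad or b.requires_grad
    if not rg:
        return Tensor(out_data)

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, True, (a, b), backward)


def swapaxes(x: Tensor, ax1: int, ax2: int) -> Tensor:
    out_data = np.swapaxes(x.data, ax1, ax2)
    if not x.requires_grad:
        return Tensor(out_data)

    def backward(g):
        x.accumulate(np.swapaxes(g, ax1, ax2))

    return Tensor(out_data, True, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)
    if not x.requires_grad:
        return Tensor(out_data)

    def backward(g):
        x.accumulate(g.reshape(x.data.shape))

    return Tensor(out_data, True, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    rg = any(t.requires_grad for t in tensors)
    if not rg:
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.accumulate(piece)

    return Tensor(out_data, True, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)
    if not x.requires_grad:
        return Tensor(out_data)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x.accumulate(out_data * (g - dot))

    return Tensor(out_data, True, (x,), backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    """Exponential linear unit: x for x > 0, alpha*(exp(x)-1) otherwise."""
    pos = x.data > 0
    expm1 = alpha * np.expm1(np.minimum(x.data, 0.0))
    out_data = np.where(pos, x.data, expm1)
    if not x.requires_grad:
        return Tensor(out_data)

    def backward(g):
        x.accumulate(g * np.where(pos, 1.0, expm1 + alpha))

    return Tensor(out_data, True, (x,), backward)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, negative_slope * x.data)
    if not x.requires_grad:
        return Tensor(out_data)

    def backward(g):
        x.accumulate(g * np.where(pos, 1.0, negative_slope))

    return Tensor(out_data, True, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = np.where(
        x.data >= 0,
        1.0 / (1.0 + np.exp(-np.abs(x.data))),
        np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))),
    )
    if not x.requires_grad:
        return Tensor(out_data)

    def backward(g):
        x.accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, True, (x,), backward)


def max_along(x: Tensor, axis: int) -> Tensor:
    """Maximum along one axis (the axis is removed).

    Gradient flows to the first argmax only, matching the convention of
    mainstream frameworks.
    """
    out_data = x.data.max(axis=axis)
    if not x.requires_grad:
        return Tensor(out_data)
    idx = np.expand_dims(x.data.argmax(axis=axis), axis)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, np.expand_dims(g, axis), axis=axis)
        x.accumulate(gx)

    return Tensor(out_data, True, (x,), backward)
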