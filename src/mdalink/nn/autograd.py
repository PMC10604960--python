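"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the two encoder channels are provided. All
tensors are float64; gradients are accumulated into ``Tensor.grad`` by
``backward()`` on a scalar output.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "scale",
    "matmul",
    "transpose",
    "concat",
    "gather",
    "relu",
    "elu",
    "leaky_relu",
    "sigmoid",
    "log",
    "softmax",
    "layer_norm",
    "maximum",
    "mean_all",
    "sum_all",
    "dropout",
    "bce_with_logits",
]


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(order):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    # light operator sugar
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return transpose(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))
    out.backward_fn = lambda g: (
        a._accumulate(_unbroadcast(g, a.data.shape)),
        b._accumulate(_unbroadcast(g, b.data.shape)),
    )
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data - b.data, (a, b))
    out.backward_fn = lambda g: (
        a._accumulate(_unbroadcast(g, a.data.shape)),
        b._accumulate(_unbroadcast(-g, b.data.shape)),
    )
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))
    out.backward_fn = lambda g: (
        a._accumulate(_unbroadcast(g * b.data, a.data.shape)),
        b._accumulate(_unbroadcast(g * a.data, b.data.shape)),
    )
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, (a,))
    out.backward_fn = lambda g: a._accumulate(g * s)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))
    out.backward_fn = lambda g: (
        a._accumulate(g @ b.data.T),
        b._accumulate(a.data.T @ g),
    )
    return out


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.data.T, (a,))
    out.backward_fn = lambda g: a._accumulate(g.T)
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out.backward_fn = backward
    return out


def gather(table: Tensor, index: np.ndarray) -> Tensor:
    """Index rows (axis 0) of ``table`` with an arbitrary-shape integer array."""
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(table.data[index], (table,))

    def backward(g: np.ndarray) -> None:
        gt = np.zeros_like(table.data)
        if table.data.ndim == 1:
            np.add.at(gt, index, g)
        else:
            np.add.at(gt, index.ravel(), g.reshape(-1, *table.data.shape[1:]))
        table._accumulate(gt)

    out.backward_fn = backward
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), (a,))
    out.backward_fn = lambda g: a._accumulate(g * (a.data > 0))
    return out


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    y = np.where(a.data > 0, a.data, alpha * np.expm1(a.data))
    out = Tensor(y, (a,))
    out.backward_fn = lambda g: a._accumulate(g * np.where(a.data > 0, 1.0, y + alpha))
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(a.data > 0, a.data, slope * a.data), (a,))
    out.backward_fn = lambda g: a._accumulate(g * np.where(a.data > 0, 1.0, slope))
    return out


def sigmoid(a: Tensor) -> Tensor:
    y = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-a.data)), np.exp(a.data) / (1.0 + np.exp(a.data)))
    out = Tensor(y, (a,))
    out.backward_fn = lambda g: a._accumulate(g * y * (1.0 - y))
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), (a,))
    out.backward_fn = lambda g: a._accumulate(g / a.data)
    return out


def softmax(a: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, (a,))
    out.backward_fn = lambda g: a._accumulate(y * (g - (g * y).sum(axis=-1, keepdims=True)))
    return out


def layer_norm(a: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance (no affine)."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out = Tensor(xhat, (a,))

    def backward(g: np.ndarray) -> None:
        gm = g.mean(axis=-1, keepdims=True)
        gx = (g * xhat).mean(axis=-1, keepdims=True)
        a._accumulate(inv * (g - gm - xhat * gx))

    out.backward_fn = backward
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; ties route the gradient to ``a``."""
    take_a = a.data >= b.data
    out = Tensor(np.where(take_a, a.data, b.data), (a, b))
    out.backward_fn = lambda g: (
        a._accumulate(g * take_a),
        b._accumulate(g * ~take_a),
    )
    return out


def mean_all(a: Tensor) -> Tensor:
    out = Tensor(np.array(a.data.mean()), (a,))
    out.backward_fn = lambda g: a._accumulate(np.full_like(a.data, float(g) / a.data.size))
    return out


def sum_all(a: Tensor) -> Tensor:
    out = Tensor(np.array(a.data.sum()), (a,))
    out.backward_fn = lambda g: a._accumulate(np.full_like(a.data, float(g)))
    return out


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p == 0.0:
        return a
    keep = (rng.random(a.data.shape) >= p) / (1.0 - p)
    out = Tensor(a.data * keep, (a,))
    out.backward_fn = lambda g: a._accumulate(g * keep)
    return out


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from raw scores."""
    z = logits.data
    y = np.asarray(labels, dtype=np.float64)
    loss = np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(np.array(loss.mean()), (logits,))
    p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    out.backward_fn = lambda g: logits._accumulate(float(g) * (p - y) / z.size)
    return out
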