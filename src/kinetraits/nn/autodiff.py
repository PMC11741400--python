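"""Reverse-mode automatic differentiation over numpy arrays.

Only the operations the trait models need are provided: broadcasting
add/mul, matmul, tanh/sigmoid, column slicing and concatenation, softmax,
layer normalization, absolute value and reductions.
"""

from __future__ import annotations

import numpy as np

_LN_EPS = 1e-12


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, _parents: tuple = ()):  # noqa: ANN001
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward() -> None:
            self._accumulate(_unbroadcast(out.grad, self.data.shape))
            other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = backward
        return out

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward() -> None:
            self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, (self, other))

        def backward() -> None:
            self._accumulate(out.grad @ other.data.T)
            other._accumulate(self.data.T @ out.grad)

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- nonlinearities -----------------------------------------------------

    def tanh(self) -> "Tensor":
        value = np.tanh(self.data)
        out = Tensor(value, (self,))

        def backward() -> None:
            self._accumulate(out.grad * (1.0 - value**2))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        value = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(value, (self,))

        def backward() -> None:
            self._accumulate(out.grad * value * (1.0 - value))

        out._backward = backward
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), (self,))

        def backward() -> None:
            self._accumulate(out.grad * np.sign(self.data))

        out._backward = backward
        return out

    # -- shape ops ----------------------------------------------------------

    def cols(self, start: int, stop: int) -> "Tensor":
        """Column slice [:, start:stop]."""
        out = Tensor(self.data[:, start:stop], (self,))

        def backward() -> None:
            grad = np.zeros_like(self.data)
            grad[:, start:stop] = out.grad
            self._accumulate(grad)

        out._backward = backward
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), (self,))

        def backward() -> None:
            self._accumulate(np.full_like(self.data, out.grad))

        out._backward = backward
        return out

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean(), (self,))

        def backward() -> None:
            self._accumulate(np.full_like(self.data, out.grad / self.data.size))

        out._backward = backward
        return out

    # -- autodiff driver ----------------------------------------------------

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            order.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward()


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (only axis=1 is needed/supported)."""
    if axis != 1:
        raise NotImplementedError("only axis=1 concatenation is supported")
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors))
    widths = [t.data.shape[1] for t in tensors]

    def backward() -> None:
        start = 0
        for t, w in zip(tensors, widths):
            t._accumulate(out.grad[:, start : start + w])
            start += w

    out._backward = backward
    return out


def softmax(x: Tensor) -> Tensor:
    """Row-wise softmax (axis=1)."""
    shifted = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    value = e / e.sum(axis=1, keepdims=True)
    out = Tensor(value, (x,))

    def backward() -> None:
        dot = (out.grad * value).sum(axis=1, keepdims=True)
        x._accumulate(value * (out.grad - dot))

    out._backward = backward
    return out


def layer_norm_raw(x: Tensor, eps: float = _LN_EPS) -> Tensor:
    """Parameter-free layer normalization along the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    value = (x.data - mu) * inv
    out = Tensor(value, (x,))
    d = x.data.shape[-1]

    def backward() -> None:
        g = out.grad
        gm = g.mean(axis=-1, keepdims=True)
        gym = (g * value).mean(axis=-1, keepdims=True)
        x._accumulate(inv * (g - gm - value * gym))

    out._backward = backward
    del d
    return out


def layer_norm_array(x: np.ndarray, eps: float = _LN_EPS) -> np.ndarray:
    """Numpy-only counterpart of :func:`layer_norm_raw` (no gradient)."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)
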