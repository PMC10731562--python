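"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the neural components of the package: dense layers,
multi-head self-attention, layer normalization, softmax losses. Tensors wrap
float64 ndarrays; the graph is taped through closures and backpropagated in
reverse topological order. Broadcasting follows NumPy semantics, with
gradients summed back to each operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "embedding_lookup", "concat_params", "no_grad_data"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- helpers -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.requires_grad:
            g = _unbroadcast(grad, self.data.shape)
            self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            self._accum(out.grad)
            other._accum(out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            self._accum(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward():
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / other.data**2)

        out = self._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward():
            self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            a, b = self.data, other.data
            ga = out.grad @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ out.grad
            self._accum(ga)
            other._accum(gb)

        out = self._make(out_data, (self, other), backward)
        return out

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            self._accum(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            self._accum(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward():
            self._accum(out.grad * mask)

        out = self._make(self.data * mask, (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward():
            self._accum(out.grad * (1.0 - out_data**2))

        out = self._make(out_data, (self,), backward)
        return out

    def abs(self):
        sign = np.sign(self.data)

        def backward():
            self._accum(out.grad * sign)

        out = self._make(np.abs(self.data), (self,), backward)
        return out

    # -- reductions / shape ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward():
            self._accum(out.grad.reshape(orig))

        out = self._make(self.data.reshape(*shape), (self,), backward)
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward():
            self._accum(out.grad.transpose(*inv))

        out = self._make(self.data.transpose(*axes), (self,), backward)
        return out

    # -- composites -------------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        shift = np.max(self.data, axis=axis, keepdims=True)  # constant
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- autodiff driver ---------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def item(self) -> float:
        return float(self.data)


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids, dtype=np.int64)
    out_data = table.data[ids]

    def backward():
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, ids.reshape(-1), out.grad.reshape(-1, table.data.shape[-1]))
            table._accum(g)

    out = table._make(out_data, (table,), backward)
    return out


def concat_params(params: Iterable[Tensor]) -> np.ndarray:
    """Flatten parameter values into one vector (for hashing/round-trips)."""
    return np.concatenate([p.data.reshape(-1) for p in params])


def no_grad_data(params: Sequence[Tensor]) -> list[np.ndarray]:
    return [p.data.copy() for p in params]
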