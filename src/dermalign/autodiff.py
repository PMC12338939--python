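"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for the desk-scale encoders and the composite
training objective: broadcasting arithmetic, matmul, relu, exp/log/sqrt/
abs, reductions, reshape/transpose, advanced indexing and concatenation.
Gradients are accumulated by a topological-order backward pass.

Design constraints: float64 throughout (the cohorts are small, stability
beats speed), no in-place graph mutation, and every op's backward is a
closed-form NumPy expression so the whole graph stays dependency-free.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = ["Tensor", "as_tensor", "cat", "relu", "exp", "log", "sqrt"]

ArrayLike = Union["Tensor", np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array node in a reverse-mode computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # make ndarray.__op__ defer to Tensor

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward=None,
    ) -> None:
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad for p in parents)
        return Tensor(data, rg, parents if rg else (), backward if rg else None)

    def __add__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        out = self._make(self.data + o.data, (self, o), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        out = self._make(self.data * o.data, (self, o), None)

        def backward(g):
            return (
                _unbroadcast(g * o.data, self.shape),
                _unbroadcast(g * self.data, o.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        out = self._make(self.data / o.data, (self, o), None)

        def backward(g):
            return (
                _unbroadcast(g / o.data, self.shape),
                _unbroadcast(-g * self.data / (o.data**2), o.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        assert np.isscalar(exponent)
        out = self._make(self.data**exponent, (self,), None)
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        out = self._make(self.data @ o.data, (self, o), None)

        def backward(g):
            return (g @ o.data.T, self.data.T @ g)

        out._backward = backward
        return out

    # ------------------------------------------------------------------
    def relu(self) -> "Tensor":
        out = self._make(np.maximum(self.data, 0.0), (self,), None)
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def exp(self) -> "Tensor":
        data = np.exp(self.data)
        out = self._make(data, (self,), None)
        out._backward = lambda g: (g * data,)
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self) -> "Tensor":
        data = np.sqrt(self.data)
        out = self._make(data, (self,), None)
        out._backward = lambda g: (g / (2.0 * data),)
        return out

    def abs(self) -> "Tensor":
        out = self._make(np.abs(self.data), (self,), None)
        out._backward = lambda g: (g * np.sign(self.data),)
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(a % self.data.ndim for a in axes)
                for a in sorted(axes):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max of the values as a constant (for log-sum-exp shifts)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = self._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: (g.transpose(inv),)
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose(tuple(range(self.ndim))[::-1])

    def __getitem__(self, idx) -> "Tensor":
        out = self._make(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # ------------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every graph leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = np.asarray(pg, dtype=np.float64)


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def cat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to each part."""
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    rg = any(t.requires_grad for t in ts)
    out = Tensor(data, rg, ts if rg else (), None)
    if rg:
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    return as_tensor(x).relu()


def exp(x: Tensor) -> Tensor:
    return as_tensor(x).exp()


def log(x: Tensor) -> Tensor:
    return as_tensor(x).log()


def sqrt(x: Tensor) -> Tensor:
    return as_tensor(x).sqrt()
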