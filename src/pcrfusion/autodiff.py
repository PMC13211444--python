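"""Reverse-mode automatic differentiation on NumPy arrays.

The network components in this package (volumetric transformer encoder,
cross-modal attention, contrast-aware enhancement, losses) are trained by
gradient descent, so they need exact gradients of scalar losses with respect
to every parameter.  This module provides a small tape-based autodiff engine:
a :class:`Tensor` wraps a ``float64`` ndarray and records the operations
applied to it; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients.

All operations support NumPy-style broadcasting; gradients are un-broadcast
(summed over broadcast axes) on the way back.  The op set is intentionally
minimal — exactly what the model architecture requires.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "sigmoid", "softmax", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- introspection -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.shape)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += -g

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.shape)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):  # pragma: no cover - not needed
            raise TypeError("tensor exponents are not supported")

        def backward(g, a=self, p=float(exponent)):
            if a.requires_grad:
                a.grad += g * p * a.data ** (p - 1.0)

        return self._make(self.data ** float(exponent), (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a.grad += _unbroadcast(ga, a.shape)
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b.grad += _unbroadcast(gb, b.shape)

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, d=out_data):
            if a.requires_grad:
                a.grad += g * d

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g / a.data

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a.grad += np.broadcast_to(g, a.shape)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g.reshape(a.shape)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward(g, a=self, inv=tuple(inverse)):
            if a.requires_grad:
                a.grad += g.transpose(inv)

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, index):
        def backward(g, a=self, idx=index):
            if a.requires_grad:
                np.add.at(a.grad, idx, g)

        return self._make(self.data[index], (self,), backward)

    def broadcast_to(self, shape):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.shape)

        return self._make(np.broadcast_to(self.data, shape), (self,), backward)

    # -- backprop -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS topological sort
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))

        for node in order:
            if node.grad is None:
                node.grad = np.zeros_like(node.data)
        self.grad = self.grad + grad if self.grad is not None else grad.copy()
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


# -- functional layer on top of Tensor ----------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, parts=tuple(tensors), ax=axis, sp=tuple(splits)):
        for part, piece in zip(parts, np.split(g, sp, axis=ax)):
            if part.requires_grad:
                part.grad += piece

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def relu(x: Tensor) -> Tensor:
    x = Tensor._wrap(x)
    mask = (x.data > 0).astype(np.float64)

    def backward(g, a=x, m=mask):
        if a.requires_grad:
            a.grad += g * m

    return Tensor._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._wrap(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g, a=x, s=out_data):
        if a.requires_grad:
            a.grad += g * s * (1.0 - s)

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max-shift is a constant w.r.t. the graph
    (softmax is shift-invariant, so gradients are unaffected)."""
    x = Tensor._wrap(x)
    shift = x.data.max(axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """LayerNorm over the last axis.

    An all-constant input has zero variance and normalizes to zeros (epsilon
    keeps the division defined), so with default gamma=1/beta=0 the output is
    exactly zero — the convention the rest of the package relies on.
    """
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    normed = centered * (var + eps) ** -0.5
    return normed * gamma + beta
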