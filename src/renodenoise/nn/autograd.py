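"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every operation returns a :class:`Tensor` that
remembers its parents and a closure computing the parent gradients from the
output gradient.  ``Tensor.backward()`` walks the tape in reverse topological
order and accumulates ``.grad`` on every tensor that requires it.

Only the operations needed by the denoising networks are provided; each one
carries an analytic backward pass that is exercised against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "as_tensor"]

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and autodiff history."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = None,
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=_DTYPE)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other),
                     _backward=lambda g: (_unbroadcast(g, self.shape),
                                          _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other),
                     _backward=lambda g: (_unbroadcast(g * other.data, self.shape),
                                          _unbroadcast(g * self.data, other.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            inv = 1.0 / float(other)
            return Tensor(self.data * inv, _parents=(self,), _backward=lambda g: (g * inv,))
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other),
                     _backward=lambda g: (
                         _unbroadcast(g / other.data, self.shape),
                         _unbroadcast(-g * self.data / (other.data ** 2), other.shape)))
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out = Tensor(self.data ** e, _parents=(self,),
                     _backward=lambda g: (g * e * self.data ** (e - 1.0),))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other),
                     _backward=lambda g: (g @ other.data.T, self.data.T @ g))
        return out

    __matmul__ = matmul

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.data.reshape(shape), _parents=(self,),
                      _backward=lambda g: (g.reshape(old),))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(_DTYPE),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).astype(_DTYPE),)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, _parents=(self,), _backward=lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope).astype(_DTYPE)
        return Tensor(self.data * factor, _parents=(self,), _backward=lambda g: (g * factor,))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(s, _parents=(self,), _backward=lambda g: (g * s * (1.0 - s),))

    def abs(self) -> "Tensor":
        sign = np.sign(self.data).astype(_DTYPE)
        return Tensor(np.abs(self.data), _parents=(self,), _backward=lambda g: (g * sign,))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
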