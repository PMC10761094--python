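"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in this package is a few dense matrix products, elementwise
nonlinearities and reductions, trained full-batch.  A small tape-based
tensor engine keeps the whole pipeline in plain NumPy (float64) while
still providing exact gradients for the Adam optimizer.  Gradient
correctness is verified against finite differences in the test suite.

Only the operations the model needs are implemented: broadcasting
add/sub/mul/div, (batched) matmul, transpose, reshape, axis sums, relu,
tanh, sigmoid, softplus, exp, log (clamped) and sqrt.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "astensor", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    # -- graph plumbing ------------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        tracked = tuple(p for p in parents if p.requires_grad or p._prev)
        if tracked:
            out.requires_grad = True
            out._prev = tracked
            out._backward = backward
        return out

    def backward(self) -> None:
        """Accumulate gradients of `self` (a scalar) into the tape leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        def backward(g):
            self._accumulate(g)
            other._accumulate(g)
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        def backward(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        def backward(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data ** 2)
        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = astensor(other)
        a, b = self.data, other.data
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul operands must be at least 2-D; use column matrices for vectors")
        def backward(g):
            self._accumulate(g @ b.swapaxes(-1, -2))
            other._accumulate(a.swapaxes(-1, -2) @ g)
        return Tensor._make(a @ b, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    @property
    def T(self) -> "Tensor":
        def backward(g):
            self._accumulate(g.T)
        return Tensor._make(self.data.T, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        def backward(g):
            self._accumulate(g.reshape(self.data.shape))
        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape))
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        def backward(g):
            self._accumulate(g * mask)
        return Tensor._make(self.data * mask, (self,), backward)

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        def backward(g):
            self._accumulate(g * (1.0 - out ** 2))
        return Tensor._make(out, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # stable in both tails
        out = np.empty_like(self.data)
        pos = self.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out[~pos] = ex / (1.0 + ex)
        def backward(g):
            self._accumulate(g * out * (1.0 - out))
        return Tensor._make(out, (self,), backward)

    def softplus(self) -> "Tensor":
        # log(1 + e^x) = max(x, 0) + log1p(e^-|x|)
        out = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        def backward(g):
            self._accumulate(g * sig)
        return Tensor._make(out, (self,), backward)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        def backward(g):
            self._accumulate(g * out)
        return Tensor._make(out, (self,), backward)

    def log(self, clamp: float = 1e-12) -> "Tensor":
        clipped = np.maximum(self.data, clamp)
        inside = self.data >= clamp
        def backward(g):
            self._accumulate(g * inside / clipped)
        return Tensor._make(np.log(clipped), (self,), backward)

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)
        def backward(g):
            self._accumulate(g * 0.5 / out)
        return Tensor._make(out, (self,), backward)


def astensor(x) -> Tensor:
    """Wrap `x` as a constant Tensor (no-op on Tensors)."""
    return x if isinstance(x, Tensor) else Tensor(x)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Symmetric-uniform init with variance 2/(fan_in + fan_out)."""
    if len(shape) == 1:
        fan_in = fan_out = shape[0]
    else:
        fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Standard Adam over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
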