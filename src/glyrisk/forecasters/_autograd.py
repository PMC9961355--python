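"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the small forecasting networks need:
broadcast add/sub/mul, 2-D matmul, tanh, sigmoid, abs, square, mean,
basic-slice indexing, and reshape.  Gradients flow through a topologically
sorted backward pass; broadcasting in the forward direction is undone by
summation in the backward direction.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "name")

    def __init__(self, data, parents=(), backward=None, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    # --- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            _acc(self, _unbroadcast(g, self.data.shape))
            _acc(other, _unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: _acc(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            _acc(self, _unbroadcast(g * other.data, self.data.shape))
            _acc(other, _unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            _acc(self, g @ other.data.T)
            _acc(other, self.data.T @ g)

        out._backward = bwd
        return out

    # --- nonlinearities ---------------------------------------------------
    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))
        out._backward = lambda g: _acc(self, g * (1.0 - t * t))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: _acc(self, g * s * (1.0 - s))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), (self,))
        out._backward = lambda g: _acc(self, g * np.sign(self.data))
        return out

    def square(self):
        out = Tensor(self.data**2, (self,))
        out._backward = lambda g: _acc(self, g * 2.0 * self.data)
        return out

    # --- reductions / shaping --------------------------------------------
    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))
        out._backward = lambda g: _acc(self, np.full_like(self.data, g / n))
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))
        out._backward = lambda g: _acc(self, np.full_like(self.data, g))
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: _acc(self, g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _acc(self, full)

        out._backward = bwd
        return out

    # --- backward ---------------------------------------------------------
    def backward(self):
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64, copy=True)
    else:
        t.grad += g


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
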