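"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the recurrent policy network:
dense matmul, broadcast add/mul, sigmoid/tanh/exp/log, embedding gather,
log-softmax, elementwise minimum and clip, and reductions.  Gradient
correctness is verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = Tensor._coerce(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * y * (1.0 - y))

        return Tensor._make(y, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * (1.0 - y * y))

        return Tensor._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * y)

        return Tensor._make(y, (self,), backward)

    def log(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sum(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(np.broadcast_to(grad, self.shape).copy())

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(grad, out):
            if self.requires_grad:
                self._accum(np.broadcast_to(grad / n, self.shape).copy())

        return Tensor._make(self.data.mean(), (self,), backward)

    def gather_rows(self, idx: np.ndarray):
        """Embedding lookup: out[k] = self[idx[k]] (idx 1-D integer)."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(grad, out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, grad)
                self._accum(g)

        return Tensor._make(self.data[idx], (self,), backward)

    def take_along_last(self, idx: np.ndarray):
        """out[k] = self[k, idx[k]] for a 2-D tensor."""
        idx = np.asarray(idx, dtype=np.intp)
        rows = np.arange(self.data.shape[0])

        def backward(grad, out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, (rows, idx), grad)
                self._accum(g)

        return Tensor._make(self.data[rows, idx], (self,), backward)

    def log_softmax(self):
        """Row-wise log-softmax for a 2-D tensor."""
        z = self.data - self.data.max(axis=1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        y = z - lse

        def backward(grad, out):
            if self.requires_grad:
                softmax = np.exp(y)
                self._accum(grad - softmax * grad.sum(axis=1, keepdims=True))

        return Tensor._make(y, (self,), backward)

    def minimum(self, other):
        """Elementwise min; at ties the gradient flows to ``self``."""
        other = Tensor._coerce(other)
        take_self = self.data <= other.data

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * take_self, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * ~take_self, other.shape))

        return Tensor._make(np.where(take_self, self.data, other.data),
                            (self, other), backward)

    def clip(self, lo: float, hi: float):
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    def reshape(self, *shape):
        old = self.shape

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- backward pass -----------------------------------------------------

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
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

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad, node)


class Adam:
    """Adam optimizer over a dict of named Tensors."""

    def __init__(self, params: dict, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
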