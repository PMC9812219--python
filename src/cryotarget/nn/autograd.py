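"""Reverse-mode automatic differentiation over numpy arrays.

Tape-based: every operation records its parents and a backward closure; a
topological sweep accumulates gradients.  Only float64 arrays, which keeps
gradient checks tight.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "no_grad"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _GRAD_ENABLED[-1]
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities & reductions ------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            return (g * s * (1.0 - s),)

        return Tensor._make(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            return (g * e,)

        return Tensor._make(e, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sum(self):
        def backward(g):
            return (np.full(self.shape, g),)

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            return (np.full(self.shape, g / n),)

        return Tensor._make(self.data.mean(), (self,), backward)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- backward pass ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("tensor does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)

        # iterative topological sort (deep graphs exceed recursion limits)
        topo: list[Tensor] = []
        state: dict[int, int] = {}  # 0/absent = unvisited, 1 = open, 2 = done
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[id(node)] = 2
                topo.append(node)
                continue
            if state.get(id(node)) is not None or not node.requires_grad:
                continue
            state[id(node)] = 1
            stack.append((node, True))
            for p in node._parents:
                if state.get(id(p)) is None and p.requires_grad:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = np.zeros_like(node.data)
            node.grad = node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self) -> None:
        self.grad = None
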