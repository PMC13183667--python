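"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The models in this package are small (a few dense matrices, one sparse
propagation operator) and are trained full-batch on a single CPU, so a compact
tape-based engine is all that is needed.  Only the operations the models use
are implemented: broadcast arithmetic, matrix products (including products
with a constant ``scipy.sparse`` operator), elementwise nonlinearities,
reductions, axis-max with argmax routing, slicing/gather, reshape and concat.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which runs the tape in reverse topological order.  Correctness is established
by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "matmul", "sparse_matmul",
    "relu", "sigmoid", "log", "exp", "power",
    "tsum", "tmean", "max_axis", "concat", "reshape", "take",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
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

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep tapes must not hit recursion limits
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return take(self, key)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- arithmetic ---------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))
    return Tensor._result(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(-g, b.data.shape)))
    return Tensor._result(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return ((a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)))
    return Tensor._result(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return ((a, _unbroadcast(g / b.data, a.data.shape)),
                (b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))
    return Tensor._result(a.data / b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        return ((a, -g),)
    return Tensor._result(-a.data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product."""
    def backward(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))
    return Tensor._result(a.data @ b.data, (a, b), backward)


def sparse_matmul(P, x: Tensor) -> Tensor:
    """Product ``P @ x`` with a constant (non-trainable) sparse/dense operator."""
    def backward(g):
        return ((x, P.T @ g),)
    return Tensor._result(P @ x.data, (x,), backward)


# -- nonlinearities -----------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        return ((a, g * mask),)
    return Tensor._result(np.where(mask, a.data, 0.0), (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def backward(g):
        return ((a, g * s * (1.0 - s)),)
    return Tensor._result(s, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        return ((a, g / a.data),)
    return Tensor._result(np.log(a.data), (a,), backward)


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)

    def backward(g):
        return ((a, g * e),)
    return Tensor._result(e, (a,), backward)


def power(a: Tensor, p: float) -> Tensor:
    def backward(g):
        return ((a, g * p * np.power(a.data, p - 1)),)
    return Tensor._result(np.power(a.data, p), (a,), backward)


# -- reductions / shaping -----------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g2, a.data.shape).copy()),)
    return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def max_axis(a: Tensor, axis: int) -> Tensor:
    """Max along one axis; gradient routed to the first argmax."""
    idx = np.argmax(a.data, axis=axis)
    out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis),
                          np.expand_dims(g, axis), axis=axis)
        return ((a, ga),)
    return Tensor._result(out, (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(zip(tensors, np.split(g, splits, axis=axis)))
    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tensors, backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        return ((a, g.reshape(a.data.shape)),)
    return Tensor._result(a.data.reshape(shape), (a,), backward)


def take(a: Tensor, key) -> Tensor:
    """Basic or integer-array indexing; gradient scattered with ``np.add.at``."""
    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, key, g)
        return ((a, ga),)
    return Tensor._result(a.data[key], (a,), backward)


# -- optimizer ----------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
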