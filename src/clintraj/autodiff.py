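"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the training objective needs: broadcasting
arithmetic, matrix products, ReLU / sigmoid / exp / log, reductions, row
softmax, indexing and concatenation.  Gradients are accumulated by a
topological-order backward sweep.

The module-level helpers (:func:`relu`, :func:`exp`, ...) dispatch on input
type so that model code can be written once and executed either on plain
ndarrays (fast, gradient-free evaluation) or on :class:`Tensor` (training).
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    # make ndarray <op> Tensor dispatch to the reflected Tensor operator
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._prev = _prev
        self._backward = _backward
        # leaves that are plain constants need no gradient work
        self.needs_grad = requires_grad or bool(_prev)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing ----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if not self.needs_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def back():
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def back():
            if self.needs_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.needs_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def back():
            a, b, g = self.data, other.data, out.grad
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
            elif a.ndim == 1:
                self._accum(g @ b.T)
                if other.needs_grad:
                    other._accum(np.outer(a, g))
            elif b.ndim == 1:
                if self.needs_grad:
                    self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            else:
                if self.needs_grad:
                    self._accum(g @ b.T)
                if other.needs_grad:
                    other._accum(a.T @ g)

        out._backward = back
        return out

    def __rmatmul__(self, other):
        return Tensor(other) @ self

    @property
    def T(self):
        out = Tensor(self.data.T, _prev=(self,))
        out._backward = lambda: self._accum(out.grad.T)
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _prev=(self,))

        def back():
            g = np.zeros_like(self.data)
            np.add.at(g, key, out.grad)
            self._accum(g)

        out._backward = back
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def back():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    def item(self) -> float:
        return float(self.data)


# -- dispatching functional API --------------------------------------------


def _is_t(x) -> bool:
    return isinstance(x, Tensor)


def relu(x):
    if _is_t(x):
        out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))
        out._backward = lambda: x._accum(out.grad * (x.data > 0))
        return out
    return np.maximum(x, 0.0)


def exp(x):
    if _is_t(x):
        out = Tensor(np.exp(x.data), _prev=(x,))
        out._backward = lambda: x._accum(out.grad * out.data)
        return out
    return np.exp(x)


def log(x):
    if _is_t(x):
        out = Tensor(np.log(x.data), _prev=(x,))
        out._backward = lambda: x._accum(out.grad / x.data)
        return out
    return np.log(x)


def sigmoid(x):
    if _is_t(x):
        s = 1.0 / (1.0 + np.exp(-x.data))
        out = Tensor(s, _prev=(x,))
        out._backward = lambda: x._accum(out.grad * s * (1 - s))
        return out
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def maximum0(x):
    """Hinge: elementwise max(0, x)."""
    return relu(x)


def softmax(x, axis: int = -1):
    """Numerically stable softmax along ``axis``."""
    if _is_t(x):
        shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
        e = exp(shifted)
        return e / e.sum(axis=axis, keepdims=True)
    x = np.asarray(x, dtype=float)
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def stack(xs, axis: int = 0):
    if any(_is_t(x) for x in xs):
        ts = [x if _is_t(x) else Tensor(x) for x in xs]
        out = Tensor(np.stack([t.data for t in ts], axis=axis), _prev=tuple(ts))

        def back():
            for i, t in enumerate(ts):
                t._accum(np.take(out.grad, i, axis=axis))

        out._backward = back
        return out
    return np.stack(xs, axis=axis)


def asdata(x) -> np.ndarray:
    return x.data if _is_t(x) else np.asarray(x)


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
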