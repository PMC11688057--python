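"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical substrate for the network in :mod:`gaitfreeze.cba_bilstm`:
a tape of :class:`Tensor` nodes, each holding a value and vector-Jacobian
closures toward its parents.  Only the operations the model needs are
implemented (elementwise arithmetic and nonlinearities, matmul with leading
batch axes, reductions, slicing/padding/concatenation, elementwise maximum
for pooling).  Gradients are exact and are verified against central finite
differences in the test suite.

Conventions: float64 throughout; broadcasting follows NumPy and gradients
are summed back over broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("value", "grad", "requires_grad", "_vjps")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, vjp: grad_out -> grad_parent)
        self._vjps: list[tuple["Tensor", Callable[[Array], Array]]] = []

    # -- construction -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- backward pass ------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        """Accumulate gradients of this (scalar unless ``grad`` given) node."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs from BPTT can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._vjps:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node._vjps:
                pg = vjp(g)
                # never accumulate in place: vjps may return views of / the
                # very arrays stored under other keys (e.g. add passes the
                # incoming gradient through unchanged)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(value: Array, parents: Sequence[tuple[Tensor, Callable[[Array], Array]]]) -> Tensor:
    out = Tensor(value)
    out._vjps = [(p, f) for p, f in parents if p.requires_grad or p._vjps]
    return out


# ---------------------------------------------------------------------------
# Elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.value + b.value,
        [
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ],
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.value * b.value,
        [
            (a, lambda g: _unbroadcast(g * b.value, a.shape)),
            (b, lambda g: _unbroadcast(g * a.value, b.shape)),
        ],
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.value / b.value,
        [
            (a, lambda g: _unbroadcast(g / b.value, a.shape)),
            (b, lambda g: _unbroadcast(-g * a.value / b.value**2, b.shape)),
        ],
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    return _node(a.value**p, [(a, lambda g: g * p * a.value ** (p - 1))])


def exp(a) -> Tensor:
    a = as_tensor(a)
    val = np.exp(a.value)
    return _node(val, [(a, lambda g: g * val)])


def log(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.log(a.value), [(a, lambda g: g / a.value)])


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    val = np.sqrt(a.value)
    return _node(val, [(a, lambda g: g * 0.5 / val)])


def tanh(a) -> Tensor:
    a = as_tensor(a)
    val = np.tanh(a.value)
    return _node(val, [(a, lambda g: g * (1.0 - val**2))])


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    val = 1.0 / (1.0 + np.exp(-a.value))
    return _node(val, [(a, lambda g: g * val * (1.0 - val))])


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0
    return _node(np.where(mask, a.value, 0.0), [(a, lambda g: g * mask)])


def maximum(a, b) -> Tensor:
    """Elementwise max; on ties the gradient flows to the first argument."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.value >= b.value
    return _node(
        np.where(take_a, a.value, b.value),
        [
            (a, lambda g: _unbroadcast(g * take_a, a.shape)),
            (b, lambda g: _unbroadcast(g * ~take_a, b.shape)),
        ],
    )


# ---------------------------------------------------------------------------
# Linear algebra, reductions, shaping
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def grad_a(g: Array) -> Array:
        return _unbroadcast(g @ b.value.swapaxes(-1, -2), a.shape)

    def grad_b(g: Array) -> Array:
        return _unbroadcast(a.value.swapaxes(-1, -2) @ g, b.shape)

    return _node(a.value @ b.value, [(a, grad_a), (b, grad_b)])


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    axes = axis if axis is None or isinstance(axis, tuple) else (axis,)

    def vjp(g: Array) -> Array:
        if axes is not None and not keepdims:
            g = np.expand_dims(g, axes)
        return np.broadcast_to(g, a.shape).copy()

    return _node(a.value.sum(axis=axis, keepdims=keepdims), [(a, vjp)])


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(a.value.reshape(shape), [(a, lambda g: g.reshape(a.shape))])


def getitem(a, key) -> Tensor:
    a = as_tensor(a)

    def vjp(g: Array) -> Array:
        out = np.zeros(a.shape)
        np.add.at(out, key, g)
        return out

    return _node(a.value[key], [(a, vjp)])


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i: int):
        lo, hi = offsets[i], offsets[i + 1]

        def vjp(g: Array) -> Array:
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        return vjp

    return _node(
        np.concatenate([t.value for t in tensors], axis=axis),
        [(t, make_vjp(i)) for i, t in enumerate(tensors)],
    )


def pad(a, pad_width) -> Tensor:
    """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
    a = as_tensor(a)

    def vjp(g: Array) -> Array:
        sl = tuple(slice(lo, g.shape[i] - hi) for i, (lo, hi) in enumerate(pad_width))
        return g[sl]

    return _node(np.pad(a.value, pad_width), [(a, vjp)])


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max subtracted as a constant)."""
    a = as_tensor(a)
    shift = a - Tensor(a.value.max(axis=axis, keepdims=True))
    e = exp(shift)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Parameters and Adam
# ---------------------------------------------------------------------------

def parameter(value) -> Tensor:
    t = Tensor(value, requires_grad=True)
    return t


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
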