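"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training losses used here (hinge losses on ball geometry, binary
cross-entropy through a residual MLP with batch normalization) need
gradients of modest computational graphs.  This module provides a small
tape-based engine: a :class:`Tensor` wraps an ``ndarray`` and records the
operations applied to it; :meth:`Tensor.backward` accumulates gradients by
reverse topological traversal.

All functional ops (``add``, ``matmul``, ``relu``, ``softplus``...) accept
either :class:`Tensor` or plain ``ndarray``/scalar arguments and return a
plain array when no argument carries a tape.  Code written against these
functions therefore runs identically in "evaluation" mode (pure numpy) and
"training" mode (differentiable), which keeps the geometric loss formulas
defined in exactly one place.

Gradients are checked against central finite differences in the test
suite; broadcasting is supported and gradients are summed back over the
broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "matmul", "power",
    "exp", "log", "sqrt", "square", "absolute",
    "relu", "sigmoid", "softplus",
    "maximum", "minimum",
    "tsum", "tmean", "take_rows", "l2norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with a gradient tape."""

    __slots__ = ("value", "grad", "_parents", "_backward", "name")

    def __init__(self, value, parents=(), backward=None, name=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, name={self.name})"

    # -- arithmetic sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, k):
        return power(self, k)

    def __getitem__(self, idx):
        return take_rows(self, idx)

    # -- backprop --------------------------------------------------------
    def backward(self, seed=None):
        """Accumulate gradients of ``self`` into every upstream Tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value) if seed is None else np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def _is_tensor(*args) -> bool:
    return any(isinstance(a, Tensor) for a in args)


def as_tensor(x, name=None) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, name=name)


def _val(x):
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _accum(t: Tensor, g: np.ndarray):
    g = _unbroadcast(g, t.value.shape)
    t.grad = g if t.grad is None else t.grad + g


def _binary(a, b, out, da, db):
    """Build a Tensor for a binary op with closure gradients da/db."""
    parents = tuple(x for x in (a, b) if isinstance(x, Tensor))

    def backward(g):
        if isinstance(a, Tensor):
            _accum(a, da(g))
        if isinstance(b, Tensor):
            _accum(b, db(g))

    return Tensor(out, parents, backward)


def _unary(a, out, da):
    def backward(g):
        _accum(a, da(g))

    return Tensor(out, (a,), backward)


# -- elementwise arithmetic ----------------------------------------------

def add(a, b):
    if not _is_tensor(a, b):
        return _val(a) + _val(b)
    return _binary(a, b, _val(a) + _val(b), lambda g: g, lambda g: g)


def sub(a, b):
    if not _is_tensor(a, b):
        return _val(a) - _val(b)
    return _binary(a, b, _val(a) - _val(b), lambda g: g, lambda g: -g)


def mul(a, b):
    if not _is_tensor(a, b):
        return _val(a) * _val(b)
    av, bv = _val(a), _val(b)
    return _binary(a, b, av * bv, lambda g: g * bv, lambda g: g * av)


def div(a, b):
    if not _is_tensor(a, b):
        return _val(a) / _val(b)
    av, bv = _val(a), _val(b)
    return _binary(a, b, av / bv, lambda g: g / bv, lambda g: -g * av / bv ** 2)


def neg(a):
    if not _is_tensor(a):
        return -_val(a)
    return _unary(a, -a.value, lambda g: -g)


def power(a, k):
    if not _is_tensor(a):
        return _val(a) ** k
    av = a.value
    return _unary(a, av ** k, lambda g: g * k * av ** (k - 1))


def square(a):
    return power(a, 2)


def matmul(a, b):
    if not _is_tensor(a, b):
        return _val(a) @ _val(b)
    av, bv = _val(a), _val(b)
    return _binary(a, b, av @ bv, lambda g: g @ bv.T, lambda g: av.T @ g)


# -- elementwise nonlinearities ------------------------------------------

def exp(a):
    if not _is_tensor(a):
        return np.exp(_val(a))
    out = np.exp(a.value)
    return _unary(a, out, lambda g: g * out)


def log(a):
    if not _is_tensor(a):
        return np.log(_val(a))
    return _unary(a, np.log(a.value), lambda g: g / a.value)


def sqrt(a):
    if not _is_tensor(a):
        return np.sqrt(_val(a))
    out = np.sqrt(a.value)
    return _unary(a, out, lambda g: g / (2.0 * out))


def absolute(a):
    if not _is_tensor(a):
        return np.abs(_val(a))
    return _unary(a, np.abs(a.value), lambda g: g * np.sign(a.value))


def relu(a):
    if not _is_tensor(a):
        return np.maximum(_val(a), 0.0)
    mask = a.value > 0
    return _unary(a, np.where(mask, a.value, 0.0), lambda g: g * mask)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # stable in both tails
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(a):
    if not _is_tensor(a):
        return _sigmoid(np.atleast_1d(_val(a)).astype(float)) if np.ndim(a) == 0 else _sigmoid(_val(a))
    out = _sigmoid(a.value)
    return _unary(a, out, lambda g: g * out * (1.0 - out))


def softplus(a):
    """log(1 + exp(a)), computed stably; gradient is sigmoid(a)."""
    av = _val(a)
    out = np.maximum(av, 0.0) + np.log1p(np.exp(-np.abs(av)))
    if not _is_tensor(a):
        return out
    return _unary(a, out, lambda g: g * _sigmoid(a.value))


def maximum(a, b):
    if not _is_tensor(a, b):
        return np.maximum(_val(a), _val(b))
    av, bv = _val(a), _val(b)
    amask = av >= bv  # ties route the gradient to the first argument
    return _binary(a, b, np.maximum(av, bv),
                   lambda g: g * amask, lambda g: g * ~amask)


def minimum(a, b):
    if not _is_tensor(a, b):
        return np.minimum(_val(a), _val(b))
    av, bv = _val(a), _val(b)
    amask = av <= bv
    return _binary(a, b, np.minimum(av, bv),
                   lambda g: g * amask, lambda g: g * ~amask)


# -- reductions and structure --------------------------------------------

def tsum(a, axis=None, keepdims=False):
    if not _is_tensor(a):
        return np.sum(_val(a), axis=axis, keepdims=keepdims)
    av = a.value
    out = av.sum(axis=axis, keepdims=keepdims)

    def da(g):
        if axis is None:
            return np.broadcast_to(g, av.shape).copy()
        g2 = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(g2, av.shape).copy()

    return _unary(a, out, da)


def tmean(a, axis=None, keepdims=False):
    av = _val(a)
    n = av.size if axis is None else av.shape[axis]
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def take_rows(a, idx):
    """Index/slice; gradients scatter-add back (repeated indices allowed)."""
    if not _is_tensor(a):
        return _val(a)[idx]
    av = a.value
    out = av[idx]

    def da(g):
        full = np.zeros_like(av)
        np.add.at(full, idx, g)
        return full

    return _unary(a, out, da)


def l2norm(a, axis=-1, eps=1e-12):
    """Euclidean norm along ``axis``; eps keeps the gradient finite at 0."""
    return sqrt(tsum(square(a), axis=axis) + eps)


class Parameter(Tensor):
    """A leaf Tensor intended to be updated by an optimizer."""

    __slots__ = ()

    def __init__(self, value, name=None):
        super().__init__(np.array(value, dtype=np.float64), name=name)


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
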