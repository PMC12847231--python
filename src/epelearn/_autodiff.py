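"""Minimal vectorized reverse-mode automatic differentiation.

The trainable components of this package (set/tabular MLP compressors, the
graph-isomorphism-network compressor, and the mixture-density heads) are tiny
networks, but their losses — negative mixture log-likelihoods composed with
pooling compressors — need exact gradients.  This module provides the small
set of differentiable array operations those architectures require, plus an
Adam optimizer.  Shapes follow numpy broadcasting; gradients of broadcast
operands are reduced back to the operand's shape.
"""

from __future__ import annotations

import numpy as np
from scipy import special


class Tensor:
    """A numpy array with an associated gradient and backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._backward = None
        self._parents = parents
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(order):
            if node._backward is not None:
                node._backward()

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _const(-1.0)))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, exponent):
        return power(self, exponent)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _const(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=float))


def _unbroadcast(grad, shape):
    """Reduce ``grad`` to ``shape`` by summing over broadcast axes."""
    grad = np.asarray(grad, dtype=float)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def parameter(data, rng=None):
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


# -- elementary operations ----------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad)
        if b.requires_grad:
            b._accumulate(out.grad)

    out._backward = _backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad * b.data)
        if b.requires_grad:
            b._accumulate(out.grad * a.data)

    out._backward = _backward
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    out = Tensor(a.data ** exponent, (a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad * exponent * a.data ** (exponent - 1))

    out._backward = _backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product supporting batched ``a`` (..., n, k) with 2-D ``b``.

    Also supports batched ``a`` with batched constant ``b`` (used for graph
    adjacency aggregation).
    """
    out = Tensor(np.matmul(a.data, b.data), (a, b))

    def _backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(np.matmul(g, np.swapaxes(b.data, -1, -2)))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = _backward
    return out


def tanh(a: Tensor) -> Tensor:
    val = np.tanh(a.data)
    out = Tensor(val, (a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad * (1.0 - val ** 2))

    out._backward = _backward
    return out


def exp(a: Tensor) -> Tensor:
    val = np.exp(a.data)
    out = Tensor(val, (a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad * val)

    out._backward = _backward
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), (a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad / a.data)

    out._backward = _backward
    return out


def gammaln(a: Tensor) -> Tensor:
    out = Tensor(special.gammaln(a.data), (a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad * special.digamma(a.data))

    out._backward = _backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad.reshape(a.data.shape))

    out._backward = _backward
    return out


def tensor_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def _backward():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = _backward
    return out


def tensor_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    count = a.data.size if axis is None else a.data.shape[axis]
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), _const(1.0 / count))


def logsumexp(a: Tensor, axis: int) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (not kept)."""
    amax = np.max(a.data, axis=axis, keepdims=True)
    shifted = a.data - amax
    sumexp = np.sum(np.exp(shifted), axis=axis, keepdims=True)
    val = (amax + np.log(sumexp)).squeeze(axis)
    out = Tensor(val, (a,))
    softmax = np.exp(shifted) / sumexp

    def _backward():
        if a.requires_grad:
            a._accumulate(np.expand_dims(out.grad, axis) * softmax)

    out._backward = _backward
    return out


def log_softmax(a: Tensor, axis: int) -> Tensor:
    return add(a, mul(_expand(logsumexp(a, axis), axis), _const(-1.0)))


def _expand(a: Tensor, axis: int) -> Tensor:
    out = Tensor(np.expand_dims(a.data, axis), (a,))

    def _backward():
        if a.requires_grad:
            a._accumulate(out.grad.squeeze(axis))

    out._backward = _backward
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Affine map on the trailing axis of ``x`` (2-D or batched 3-D)."""
    return add(matmul(x, weight), bias)


# -- optimizer -----------------------------------------------------------

class Adam:
    """Adam with the standard default moment parameters."""

    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {"t": self._t, "m": [m.copy() for m in self._m], "v": [v.copy() for v in self._v]}
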