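"""Minimal vectorized reverse-mode automatic differentiation.

The trainable backbone of this package is three linear/MLP components
optimized under a contrastive + KL objective.  This module provides exactly
the primitives that objective needs — broadcast arithmetic, matmul, exp/log,
reductions, concatenation — as a small tape-based autodiff engine over
float64 numpy arrays, plus an Adam optimizer and the layer helpers (dense,
layer norm, dropout) used by the encoder.

Everything is double precision; gradients are accumulated densely.  The
engine is deliberately sized to this model family (2-D tensors, a few
hundred thousand parameters) and makes no attempt at GPU execution.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "Adam",
    "Dense",
    "LayerNorm",
    "dropout",
    "l2_normalize_rows",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast up from `shape`."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape.

    Operations between tensors (or tensors and scalars/arrays) build a
    computation graph; calling :meth:`backward` on a scalar result fills the
    ``grad`` attribute of every tensor with ``requires_grad=True`` that
    contributed to it.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.requires_grad:
            g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
            self.grad = g if self.grad is None else self.grad + g

    # -- properties ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        def bwd(g):
            a._accum(g.T)

        a = self
        return Tensor._from_op(self.data.T, (self,), bwd)

    def __float__(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            a._accum(g)
            b._accum(g)

        return Tensor._from_op(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._from_op(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            a._accum(g * b.data)
            b._accum(g * a.data)

        return Tensor._from_op(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            a._accum(g / b.data)
            b._accum(-g * a.data / (b.data * b.data))

        return Tensor._from_op(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._from_op(a.data**p, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._from_op(a.data @ b.data, (a, b), bwd)

    # -- elementwise functions -----------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._from_op(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._from_op(out_data, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - out_data * out_data))

        return Tensor._from_op(out_data, (a,), bwd)

    def relu(self):
        a = self
        keep = a.data > 0

        def bwd(g):
            a._accum(g * keep)

        return Tensor._from_op(np.where(keep, a.data, 0.0), (a,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp with straight-through gradient inside [lo, hi]."""
        a = self
        inside = (a.data >= lo) & (a.data <= hi)

        def bwd(g):
            a._accum(g * inside)

        return Tensor._from_op(np.clip(a.data, lo, hi), (a,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff ------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis` with gradient split on the way back."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Row-wise L2 normalization (the cosine-similarity front end)."""
    norm = ((x * x).sum(axis=1, keepdims=True) + eps).sqrt()
    return x / norm


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero a `rate` fraction of entries, rescale the rest."""
    if rate <= 0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


class Dense:
    """A fully-connected layer, Glorot-uniform initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class LayerNorm:
    """Per-row layer normalization with learned gain and bias."""

    def __init__(self, n: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
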