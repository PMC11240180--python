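"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable parts of this package (message-passing encoder, radial flow
layers, the evidential loss) need gradients of scalar losses with respect to
parameter arrays.  This module provides a small tape-based engine: a
:class:`Tensor` wraps an ``ndarray`` and records the operations applied to it;
:meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the primitives used by the package are
implemented (elementwise arithmetic, matmul, reductions, gather/segment ops,
and the special functions ``digamma``/``gammaln`` needed by Dirichlet losses).

All arrays are float64.  Broadcasting follows numpy semantics; gradients are
summed back over broadcast axes.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "sigmoid",
    "softplus",
    "clip",
    "digamma",
    "gammaln",
    "tsum",
    "tmean",
    "matmul",
    "gather",
    "segment_sum",
    "segment_softmax",
    "concat",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph: value plus backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
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

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(g)
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g / b.data)
                if b.requires_grad:
                    b._accum(-g * a.data / (b.data ** 2))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = _make(self.data ** exponent, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, e=exponent: a._accum(
                g * e * a.data ** (e - 1)
            )
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return gather(self, idx)

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else ())


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """A leaf tensor tracked for gradients; optionally random-normal init."""
    if rng is not None:
        data = rng.standard_normal(data) * (scale if scale is not None else 1.0)
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


# --------------------------------------------------------------- elementwise
def _unary(x, fn, dfn):
    x = _as_tensor(x)
    y = fn(x.data)
    out = _make(y, (x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, yv=y: a._accum(g * dfn(a.data, yv))
    return out


def exp(x):
    return _unary(x, np.exp, lambda d, y: y)


def log(x):
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def sqrt(x):
    return _unary(x, np.sqrt, lambda d, y: 0.5 / y)


def tanh(x):
    return _unary(x, np.tanh, lambda d, y: 1.0 - y ** 2)


def sigmoid(x):
    return _unary(x, _sp.expit, lambda d, y: y * (1.0 - y))


def softplus(x):
    # log(1 + e^x), overflow-safe; derivative is the logistic function
    return _unary(
        x,
        lambda d: np.logaddexp(0.0, d),
        lambda d, y: _sp.expit(d),
    )


def clip(x, lo: float | None, hi: float | None):
    """Clamp values; gradient passes only through the un-clamped region."""
    x = _as_tensor(x)
    y = np.clip(x.data, lo, hi)
    out = _make(y, (x,))
    if out.requires_grad:
        mask = np.ones_like(x.data)
        if lo is not None:
            mask = mask * (x.data > lo)
        if hi is not None:
            mask = mask * (x.data < hi)
        out._backward = lambda g, a=x, m=mask: a._accum(g * m)
    return out


def digamma(x):
    return _unary(x, _sp.digamma, lambda d, y: _sp.polygamma(1, d))


def gammaln(x):
    return _unary(x, _sp.gammaln, lambda d, y: _sp.digamma(d))


# ---------------------------------------------------------------- reductions
def tsum(x, axis=None, keepdims=False):
    x = _as_tensor(x)
    out = _make(x.data.sum(axis=axis, keepdims=keepdims), (x,))
    if out.requires_grad:
        def bwd(g, a=x):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape))
        out._backward = bwd
    return out


def tmean(x, axis=None, keepdims=False):
    x = _as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return tsum(x, axis=axis, keepdims=keepdims) * (1.0 / n)


# -------------------------------------------------------------- linear / gather
def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(a.data @ b.data, (a, b))
    if out.requires_grad:
        def bwd(g, x=a, y=b):
            if x.requires_grad:
                x._accum(g @ y.data.T)
            if y.requires_grad:
                y._accum(x.data.T @ g)
        out._backward = bwd
    return out


def gather(x, idx):
    """Row (or fancy-index) selection with scatter-add backward."""
    x = _as_tensor(x)
    out = _make(x.data[idx], (x,))
    if out.requires_grad:
        def bwd(g, a=x, i=idx):
            buf = np.zeros_like(a.data)
            np.add.at(buf, i, g)
            a._accum(buf)
        out._backward = bwd
    return out


def segment_sum(x, segment_ids: np.ndarray, num_segments: int):
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    x = _as_tensor(x)
    shape = (num_segments,) + x.data.shape[1:]
    y = np.zeros(shape, dtype=np.float64)
    np.add.at(y, segment_ids, x.data)
    out = _make(y, (x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, i=segment_ids: a._accum(g[i])
    return out


def segment_softmax(scores, segment_ids: np.ndarray, num_segments: int):
    """Softmax normalized within each segment (rows sharing an id).

    The max-shift used for numerical stability is treated as a constant,
    which leaves the gradient unchanged (softmax is shift invariant).
    """
    scores = _as_tensor(scores)
    flat = scores.data.reshape(len(segment_ids), -1)
    mx = np.full((num_segments, flat.shape[1]), -np.inf)
    np.maximum.at(mx, segment_ids, flat)
    shift = mx[segment_ids].reshape(scores.data.shape)
    e = exp(scores - Tensor(shift))
    denom = segment_sum(e, segment_ids, num_segments)
    return e / gather(denom, segment_ids)


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g, ts=tensors, sp=splits, ax=axis):
            for t, piece in zip(ts, np.split(g, sp, axis=ax)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bwd
    return out


# ---------------------------------------------------------------- optimizer
class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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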