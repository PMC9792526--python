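"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the feed-forward, factorization-machine and
mixture-of-experts architectures in :mod:`qideep.models`: dense layers,
ReLU/sigmoid/softmax, elementwise arithmetic with broadcasting, row
gathering for embedding lookups, fused cross-entropy losses, dropout and an
Adam optimizer.  Everything is float64 and deterministic given the numpy
Generators passed in.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "add", "sub", "mul", "matmul",
           "relu", "sigmoid", "softmax", "concat", "gather_rows", "tsum",
           "scale", "dropout", "cross_entropy_with_logits",
           "bce_with_logits", "backward", "Adam", "Dense"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "parents", "bwd")

    def __init__(self, data, requires_grad=False, parents=(), bwd=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self.parents = parents
        self.bwd = bwd          # callable(grad_out) -> tuple of parent grads

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))
    out.bwd = lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))
    out.bwd = lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))
    out.bwd = lambda g: (_unbroadcast(g * b.data, a.shape),
                         _unbroadcast(g * a.data, b.shape))
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, parents=(a,))
    out.bwd = lambda g: (g * c,)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))
    out.bwd = lambda g: (g @ b.data.T, a.data.T @ g)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))
    out.bwd = lambda g: (g * mask,)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    out = Tensor(s, parents=(a,))
    out.bwd = lambda g: (g * s * (1.0 - s),)
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, parents=(a,))
    out.bwd = lambda g: (p * (g - (g * p).sum(axis=axis, keepdims=True)),)
    return out


def concat(parts: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis),
                 parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    cuts = np.cumsum(sizes)[:-1]
    out.bwd = lambda g: tuple(np.split(g, cuts, axis=axis))
    return out


def gather_rows(a: Tensor, idx) -> Tensor:
    """Row lookup a[idx] with scatter-add backward (embedding lookup)."""
    idx = np.asarray(idx)
    out = Tensor(a.data[idx], parents=(a,))

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)
    out.bwd = bwd
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)
    out.bwd = bwd
    return out


def dropout(a: Tensor, rate: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate <= 0.0:
        return a
    mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
    return mul(a, constant(mask))


def cross_entropy_with_logits(logits: Tensor, labels, reduction="mean") -> Tensor:
    """Multiclass cross entropy, fused with softmax for stability."""
    y = np.asarray(labels, dtype=int)
    n, C = logits.shape
    if y.min() < 0 or y.max() >= C:
        raise ValueError("class labels out of range")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    nll = -logp[np.arange(n), y]
    val = nll.sum() if reduction == "sum" else nll.mean()
    out = Tensor(val, parents=(logits,))
    p = np.exp(logp)

    def bwd(g):
        gi = p.copy()
        gi[np.arange(n), y] -= 1.0
        if reduction == "mean":
            gi /= n
        return (g * gi,)
    out.bwd = bwd
    return out


def bce_with_logits(logits: Tensor, labels, reduction="mean") -> Tensor:
    """Binary cross entropy on logits: log(1+exp(-|z|)) + max(z,0) - z*y."""
    y = np.asarray(labels, dtype=float).reshape(logits.shape)
    if ((y != 0) & (y != 1)).any():
        raise ValueError("binary labels must be 0/1")
    z = logits.data
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    val = loss.sum() if reduction == "sum" else loss.mean()
    out = Tensor(val, parents=(logits,))
    s = 1.0 / (1.0 + np.exp(-z))

    def bwd(g):
        gi = s - y
        if reduction == "mean":
            gi = gi / z.size
        return (g * gi,)
    out.bwd = bwd
    return out


def backward(loss: Tensor) -> None:
    """Reverse-topological backpropagation from a scalar loss."""
    topo, seen = [], set()

    def visit(t):
        if id(t) in seen:
            return
        seen.add(id(t))
        for p in t.parents:
            visit(p)
        topo.append(t)
    visit(loss)
    for t in topo:
        t.grad = None
    loss.grad = np.ones_like(loss.data)
    for t in reversed(topo):
        if t.bwd is None or t.grad is None:
            continue
        for p, g in zip(t.parents, t.bwd(t.grad)):
            p._accum(g)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 0.01):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)


class Dense:
    """Fully connected layer with He-uniform weight init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.W = parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def n_params(self) -> int:
        return self.W.data.size + self.b.data.size
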