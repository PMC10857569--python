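"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just the operations the searched message-passing network needs: dense
linear algebra, elementwise nonlinearities, gather/scatter over node
indices, neighbourhood aggregation (sum / mean / max) and a softmax for the
Gumbel relaxation.  Gradients are accumulated on a tape and released by
:func:`backward`; every op is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "parents", "bw", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = ()
        self.bw = None
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, bw) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out.parents = tuple(parents)
        out.bw = bw
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g, out):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g, out):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g, out):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bw)


def cmul(a: Tensor, const) -> Tensor:
    c = np.asarray(const, dtype=np.float64)

    def bw(g, out):
        if a.requires_grad:
            a._accum(_unbroadcast(g * c, a.shape))

    return _make(a.data * c, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g, out):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g, out):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(a.data * mask, (a,), bw)


def prelu(a: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a single learnable negative slope (scalar tensor)."""
    neg = a.data < 0
    data = np.where(neg, slope.data * a.data, a.data)

    def bw(g, out):
        if a.requires_grad:
            a._accum(g * np.where(neg, slope.data, 1.0))
        if slope.requires_grad:
            slope._accum(np.array((g * a.data * neg).sum()).reshape(slope.shape))

    return _make(data, (a, slope), bw)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def bw(g, out):
        if a.requires_grad:
            a._accum(g * s * (1.0 - s))

    return _make(s, (a,), bw)


def softplus(a: Tensor) -> Tensor:
    data = np.logaddexp(0.0, a.data)

    def bw(g, out):
        if a.requires_grad:
            a._accum(g / (1.0 + np.exp(-np.clip(a.data, -60, 60))))

    return _make(data, (a,), bw)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; ties route the gradient to ``a``."""
    take_a = a.data >= b.data

    def bw(g, out):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.shape))

    return _make(np.where(take_a, a.data, b.data), (a, b), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g, out):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def bw(g, out):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accum(acc)

    return _make(a.data[idx], (a,), bw)


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size

    def bw(g, out):
        if a.requires_grad:
            a._accum(np.full_like(a.data, float(g) / n))

    return _make(np.array(a.data.mean()), (a,), bw)


def softmax1d(a: Tensor) -> Tensor:
    z = a.data - a.data.max()
    e = np.exp(z)
    s = e / e.sum()

    def bw(g, out):
        if a.requires_grad:
            a._accum(s * (g - float(g @ s)))

    return _make(s, (a,), bw)


def weighted_sum(mats: list[Tensor], weights: Tensor) -> Tensor:
    """sum_i weights[i] * mats[i]; all mats share a shape, weights is 1-D."""
    if len(mats) != weights.data.shape[0]:
        raise ValueError("one weight per summand required")
    data = sum(w * m.data for w, m in zip(weights.data, mats))

    def bw(g, out):
        for i, m in enumerate(mats):
            if m.requires_grad:
                m._accum(weights.data[i] * g)
        if weights.requires_grad:
            weights._accum(np.array([(m.data * g).sum() for m in mats]))

    return _make(data, tuple(mats) + (weights,), bw)


def neighbor_agg(h: Tensor, adj: list[np.ndarray], kind: str) -> Tensor:
    """Aggregate neighbour rows of ``h`` for each node.

    ``adj[v]`` holds the neighbour indices of node v.  Empty neighbourhoods
    yield the zero vector for every ``kind``.
    """
    n, d = h.data.shape
    out_data = np.zeros((len(adj), d))
    if kind == "sum" or kind == "mean":
        for v, nb in enumerate(adj):
            if len(nb):
                s = h.data[nb].sum(axis=0)
                out_data[v] = s / len(nb) if kind == "mean" else s

        def bw(g, out):
            if h.requires_grad:
                acc = np.zeros_like(h.data)
                for v, nb in enumerate(adj):
                    if len(nb):
                        gv = g[v] / len(nb) if kind == "mean" else g[v]
                        acc[nb] += gv
                h._accum(acc)

    elif kind == "max":
        argmax = [None] * len(adj)
        for v, nb in enumerate(adj):
            if len(nb):
                vals = h.data[nb]
                am = vals.argmax(axis=0)
                argmax[v] = nb[am]
                out_data[v] = vals[am, np.arange(d)]

        def bw(g, out):
            if h.requires_grad:
                acc = np.zeros_like(h.data)
                cols = np.arange(d)
                for v, src in enumerate(argmax):
                    if src is not None:
                        np.add.at(acc, (src, cols), g[v])
                h._accum(acc)

    else:
        raise ValueError(f"unknown aggregation {kind!r}")
    return _make(out_data, (h,), bw)


def backward(loss: Tensor) -> None:
    """Reverse sweep from a scalar ``loss``."""
    topo: list[Tensor] = []
    seen: set[int] = set()

    def visit(t: Tensor) -> None:
        stack = [(t, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))

    visit(loss)
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node.bw is not None and node.grad is not None:
            node.bw(node.grad, node)


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
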