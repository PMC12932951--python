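"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the small token-level models in this package:
dense affine maps, embedding lookups, self-attention, graph attention with
segment softmax over edges, and masked cross-entropy.  Everything is float64
and single-threaded numpy, so repeated evaluation of the same graph on the
same inputs is bitwise stable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "tanh",
    "leaky_relu",
    "softmax",
    "concat",
    "gather_rows",
    "segment_softmax",
    "segment_sum",
    "reshape",
    "transpose",
    "sum_axis",
    "scale",
    "mean_rows",
    "cross_entropy",
    "backward",
]


class Tensor:
    """A node in the computation graph: a value, an optional gradient, and
    the backward closure that propagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _node(data, parents, backward_fn):
    t = Tensor(data, parents=parents, backward_fn=backward_fn)
    if not t.requires_grad:
        t._parents, t._backward = (), None
    return t


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def scale(a: Tensor, s: float) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            a._accum(g * s)

    return _node(a.data * s, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(g @ b.data.swapaxes(-1, -2))
        if b.requires_grad:
            gb = a.data.swapaxes(-1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), bwd)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * (1.0 - out_data * out_data))

    return _node(out_data, (a,), bwd)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    pos = a.data > 0
    out_data = np.where(pos, a.data, slope * a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * np.where(pos, 1.0, slope))

    return _node(out_data, (a,), bwd)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

    return _node(out_data, (a,), bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _node(out_data, tuple(tensors), bwd)


def gather_rows(a: Tensor, idx) -> Tensor:
    """Select rows ``a[idx]`` (embedding lookup / edge endpoint gather)."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def bwd(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accum(acc)

    return _node(out_data, (a,), bwd)


def segment_sum(a: Tensor, seg_ids, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets given by ``seg_ids``."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + a.data.shape[1:])
    np.add.at(out_data, seg_ids, a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g[seg_ids])

    return _node(out_data, (a,), bwd)


def segment_softmax(scores: Tensor, seg_ids, num_segments: int) -> Tensor:
    """Softmax over groups of entries sharing a segment id.

    ``scores`` has shape (E,) or (E, K); normalization is within each segment,
    independently per trailing column.
    """
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    s = scores.data
    # per-segment max for numerical stability
    hi = np.full((num_segments,) + s.shape[1:], -np.inf)
    np.maximum.at(hi, seg_ids, s)
    e = np.exp(s - hi[seg_ids])
    denom = np.zeros((num_segments,) + s.shape[1:])
    np.add.at(denom, seg_ids, e)
    out_data = e / denom[seg_ids]

    def bwd(g):
        if scores.requires_grad:
            dot = np.zeros((num_segments,) + s.shape[1:])
            np.add.at(dot, seg_ids, g * out_data)
            scores._accum(out_data * (g - dot[seg_ids]))

    return _node(out_data, (scores,), bwd)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def bwd(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), bwd)


def sum_axis(a: Tensor, axis: int) -> Tensor:
    out_data = a.data.sum(axis=axis)

    def bwd(g):
        if a.requires_grad:
            a._accum(np.broadcast_to(np.expand_dims(g, axis), a.data.shape).copy())

    return _node(out_data, (a,), bwd)


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape

    def bwd(g):
        if a.requires_grad:
            a._accum(g.reshape(orig))

    return _node(a.data.reshape(shape), (a,), bwd)


def mean_rows(a: Tensor) -> Tensor:
    """Mean over the first axis."""
    n = a.data.shape[0]

    def bwd(g):
        if a.requires_grad:
            a._accum(np.broadcast_to(g / n, a.data.shape).copy())

    return _node(a.data.mean(axis=0), (a,), bwd)


def cross_entropy(logits: Tensor, targets, mask=None) -> Tensor:
    """Mean negative log-likelihood over unmasked positions.

    ``logits``: (n, C); ``targets``: (n,) integer class ids; ``mask``: optional
    boolean (n,), False positions contribute nothing (padding contract).
    """
    targets = np.asarray(targets, dtype=np.intp)
    n = logits.data.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("cross_entropy: all positions masked out")
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    safe_t = np.where(mask, targets, 0)
    nll = -logp[np.arange(n), safe_t]
    out_data = (nll * mask).sum() / m

    def bwd(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), safe_t] -= 1.0
            p *= (mask / m)[:, None]
            logits._accum(g * p)

    return _node(out_data, (logits,), bwd)


def backward(loss: Tensor):
    """Run reverse-mode accumulation from a scalar ``loss``."""
    topo: list[Tensor] = []
    seen = set()
    stack = [(loss, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
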