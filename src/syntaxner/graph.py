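"""Typed dependency graphs and their relational graph-attention encoder.

A parsed sentence becomes a directed multigraph with one node per token.
Every head->dependent arc with relation r contributes a forward edge (typed
r->) and an inverse edge (typed r<-); every node carries a SELF loop.  The
inverse edges and self-loops make information flow in both directions along
the tree — without them, leaf tokens would receive nothing.

The encoder is a multi-headed relational graph attention network: per layer
and head, each node attends over its incoming edges with scores computed
from relation-specifically transformed source states and the target state
through a leaky-rectifier scoring function, softmax-normalized per node
across all of its incoming edges jointly.  Head outputs are concatenated,
projected, and passed through a tanh; the last layer projects to the shared
hidden size H, yielding the structured embeddings g_i consumed by the
fusion gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import Sentence
from .errors import ValidationError
from .nn import Module, glorot
from .nn import autodiff as ad


class RelationVocab:
    """Edge-type vocabulary: SELF, UNK, then r-> / r<- per dependency relation."""

    SELF = 0
    UNK = 1
    N_RESERVED = 2

    def __init__(self, deprels):
        self._types = ["<SELF>", "<UNK>"]
        self._map: dict[str, int] = {}
        for rel in deprels:
            for suffix in ("->", "<-"):
                name = rel + suffix
                if name not in self._map:
                    self._map[name] = len(self._types)
                    self._types.append(name)

    def __len__(self) -> int:
        return len(self._types)

    def id(self, deprel: str, inverse: bool) -> int:
        return self._map.get(deprel + ("<-" if inverse else "->"), self.UNK)

    def name(self, i: int) -> str:
        return self._types[i]


@dataclass
class DependencyGraph:
    n: int
    # parallel arrays: edges[e] = (src[e] -> tgt[e]) with relation rel[e]
    src: np.ndarray
    tgt: np.ndarray
    rel: np.ndarray
    unknown_relations: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.src)


def build_graph(sentence: Sentence, relations: RelationVocab) -> DependencyGraph:
    """Typed graph for one sentence: forward + inverse arcs and SELF loops.

    Deterministic edge order: all dependency arcs in token order (forward then
    inverse per token), then SELF loops in node order.  Relations absent from
    the vocabulary map to UNK and are recorded, never rejected.
    """
    n = sentence.n
    src, tgt, rel = [], [], []
    unknown: list[str] = []
    for t in sentence.tokens:
        if t.head is None or not (0 <= t.head <= n):
            raise ValidationError(f"token {t.index}: head {t.head} out of [0, {n}]")
        if t.head == 0:
            continue  # virtual root: no edge
        h, d = t.head - 1, t.index - 1
        fwd = relations.id(t.deprel, inverse=False)
        inv = relations.id(t.deprel, inverse=True)
        if fwd == RelationVocab.UNK and t.deprel is not None:
            unknown.append(t.deprel)
        src.extend([h, d])
        tgt.extend([d, h])
        rel.extend([fwd, inv])
    for i in range(n):
        src.append(i)
        tgt.append(i)
        rel.append(RelationVocab.SELF)
    if unknown:
        warnings.warn(f"unknown dependency relations mapped to UNK: {sorted(set(unknown))}")
    return DependencyGraph(n=n,
                           src=np.asarray(src, dtype=np.intp),
                           tgt=np.asarray(tgt, dtype=np.intp),
                           rel=np.asarray(rel, dtype=np.intp),
                           unknown_relations=unknown)


class RGATLayer(Module):
    def __init__(self, rng, n_relations: int, d_in: int, d_out: int, heads: int):
        if d_out % heads:
            raise ValidationError(f"hidden size {d_out} not divisible by {heads} heads")
        self.heads = heads
        self.d_head = d_out // heads
        # per-relation source transforms, all heads at once: (R, d_in, K*d_head)
        self.W_rel = ad.parameter(glorot(rng, d_in, d_out, shape=(n_relations, d_in, d_out)))
        self.U_tgt = ad.parameter(glorot(rng, d_in, d_out))
        self.a_src = ad.parameter(glorot(rng, self.d_head, 1, shape=(heads, self.d_head)))
        self.a_tgt = ad.parameter(glorot(rng, self.d_head, 1, shape=(heads, self.d_head)))
        self.W_out = ad.parameter(glorot(rng, d_out, d_out))
        self.b_out = ad.parameter(np.zeros(d_out))

    def __call__(self, x: ad.Tensor, graph: DependencyGraph) -> ad.Tensor:
        K, dh = self.heads, self.d_head
        E, n = graph.n_edges, graph.n
        # relation-specific transform of each edge's source state
        w_e = ad.gather_rows(self.W_rel, graph.rel)          # (E, d_in, K*dh)
        x_src = ad.gather_rows(x, graph.src)                 # (E, d_in)
        msg = ad.matmul(ad.reshape(x_src, (E, 1, -1)), w_e)  # (E, 1, K*dh)
        msg = ad.reshape(msg, (E, K, dh))
        # target-side transform (shared across relations)
        x_tgt = ad.gather_rows(ad.matmul(x, self.U_tgt), graph.tgt)  # (E, K*dh)
        x_tgt = ad.reshape(x_tgt, (E, K, dh))
        # additive scoring with a leaky rectifier, one score per edge and head
        s = ad.add(ad.mul(msg, ad.reshape(self.a_src, (1, K, dh))),
                   ad.mul(x_tgt, ad.reshape(self.a_tgt, (1, K, dh))))
        scores = ad.leaky_relu(ad.sum_axis(s, axis=2))        # (E, K)
        alpha = ad.segment_softmax(scores, graph.tgt, n)      # (E, K)
        weighted = ad.mul(msg, ad.reshape(alpha, (E, K, 1)))
        agg = ad.segment_sum(ad.reshape(weighted, (E, K * dh)), graph.tgt, n)  # (n, K*dh)
        return ad.tanh(ad.add(ad.matmul(agg, self.W_out), self.b_out))

    def attention(self, x_data: np.ndarray, graph: DependencyGraph) -> np.ndarray:
        """Attention weights (E, K) for inspection/testing; no gradients."""
        out = self._forward_with_alpha(x_data, graph)
        return out[1]

    def _forward_with_alpha(self, x_data, graph):
        x = ad.constant(x_data)
        K, dh, E, n = self.heads, self.d_head, graph.n_edges, graph.n
        w_e = ad.gather_rows(self.W_rel, graph.rel)
        msg = ad.reshape(ad.matmul(ad.reshape(ad.gather_rows(x, graph.src), (E, 1, -1)), w_e),
                         (E, K, dh))
        x_tgt = ad.reshape(ad.gather_rows(ad.matmul(x, self.U_tgt), graph.tgt), (E, K, dh))
        s = ad.add(ad.mul(msg, ad.reshape(self.a_src, (1, K, dh))),
                   ad.mul(x_tgt, ad.reshape(self.a_tgt, (1, K, dh))))
        scores = ad.leaky_relu(ad.sum_axis(s, axis=2))
        alpha = ad.segment_softmax(scores, graph.tgt, n)
        return None, alpha.data


class RGATEncoder(Module):
    """Stack of RGAT layers with a final projection to hidden size H."""

    def __init__(self, rng: np.random.Generator, n_relations: int, d_in: int,
                 hidden: int, layers: int = 2, heads: int = 4, residual: bool = False):
        self.residual = residual
        dims = [d_in] + [hidden] * layers
        self.layers = [RGATLayer(rng, n_relations, dims[i], dims[i + 1], heads)
                       for i in range(layers)]
        self.W_proj = ad.parameter(glorot(rng, hidden, hidden))
        self.b_proj = ad.parameter(np.zeros(hidden))

    def __call__(self, x: ad.Tensor, graph: DependencyGraph) -> ad.Tensor:
        h = x
        for i, layer in enumerate(self.layers):
            out = layer(h, graph)
            if self.residual and i > 0:
                out = ad.add(out, h)
            h = out
        return ad.add(ad.matmul(h, self.W_proj), self.b_proj)


def rgat_encode(features: np.ndarray, graph: DependencyGraph, encoder: RGATEncoder) -> np.ndarray:
    """Encode node features along the typed dependency graph (no gradients).

    Returns the n x H matrix of structured embeddings g_i.
    """
    feats = np.asarray(features, dtype=np.float64)
    if feats.shape[0] != graph.n:
        raise ValidationError(f"feature rows {feats.shape[0]} != node count {graph.n}")
    if not np.all(np.isfinite(feats)):
        raise ValidationError("non-finite feature values")
    return encoder(ad.constant(feats), graph).data
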