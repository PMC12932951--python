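"""Syntactic vectors from linearized parse labels (pathway 2).

Each token's (head_code, deprel) label is embedded component-wise — the two
vocabularies differ hugely in size, so head codes and relations get separate
tables — then the concatenation is projected to the shared hidden size H
through a tanh.  The embedder itself is position independent: positional
information lives entirely in the head code.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ValidationError
from .linearize import LabelVocab, SyntaxLabel
from .nn import Embedding, Linear, Module
from .nn import autodiff as ad


class SyntaxLabelEmbedder(Module):
    """Maps n syntax labels to an n x H matrix of syntactic vectors g_i."""

    def __init__(self, rng: np.random.Generator, head_vocab: LabelVocab,
                 rel_vocab: LabelVocab, hidden: int,
                 head_dim: int = 64, rel_dim: int = 32):
        self.head_vocab = head_vocab
        self.rel_vocab = rel_vocab
        self.head_emb = Embedding(rng, len(head_vocab), head_dim)
        self.rel_emb = Embedding(rng, len(rel_vocab), rel_dim)
        self.proj = Linear(rng, head_dim + rel_dim, hidden)

    def label_ids(self, labels: Sequence[SyntaxLabel]) -> tuple[np.ndarray, np.ndarray]:
        head_ids = np.array([self.head_vocab.id(l.head_code) for l in labels], dtype=np.intp)
        rel_ids = np.array([self.rel_vocab.id(l.deprel) for l in labels], dtype=np.intp)
        return head_ids, rel_ids

    def forward(self, labels: Sequence[SyntaxLabel]) -> ad.Tensor:
        if len(labels) == 0:
            raise ValidationError("cannot embed an empty label sequence")
        head_ids, rel_ids = self.label_ids(labels)
        z = ad.concat([self.head_emb(head_ids), self.rel_emb(rel_ids)], axis=-1)
        return ad.tanh(self.proj(z))


def embed_syntax_labels(labels: Sequence[SyntaxLabel], embedder: SyntaxLabelEmbedder) -> np.ndarray:
    """Deterministic n x H embedding of a label sequence (no gradients)."""
    return embedder.forward(labels).data
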