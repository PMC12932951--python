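"""Dependency trees as one label per token, and back.

Two head encodings are supported, both pairing a head code with the
dependency relation:

* **relative** — the head code is the signed offset head − index ("+1",
  "-2"), with the reserved symbol "R" for root attachment.  Position
  independent, so the label space stays compact.
* **absolute** — the head code is the head's 1-based sentence position as
  printed ("0" for the root).

Decoding is total: any label sequence of the right length decodes, with
out-of-range or self-referential heads repaired to the virtual root and
flagged.  Repairing to the root never creates cycles, which is the standard
fallback for sequence-labelling parsers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .corpus import Sentence
from .errors import ValidationError

Scheme = Literal["relative", "absolute"]

ROOT_CODE = "R"
SCHEMES = ("relative", "absolute")


def _check_scheme(scheme: str) -> None:
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


@dataclass(frozen=True)
class SyntaxLabel:
    """Per-token linearized parse fragment: head code + relation."""

    head_code: str
    deprel: str

    def joint(self) -> str:
        return f"{self.head_code}␟{self.deprel}"  # unit separator, never in deprels

    @staticmethod
    def from_joint(s: str) -> "SyntaxLabel":
        code, _, rel = s.partition("␟")
        return SyntaxLabel(code, rel)


def encode_dependencies(sentence: Sentence, scheme: Scheme) -> list[SyntaxLabel]:
    """Encode a parsed sentence as one :class:`SyntaxLabel` per token."""
    _check_scheme(scheme)
    n = sentence.n
    labels = []
    for t in sentence.tokens:
        if t.head is None or not (0 <= t.head <= n):
            raise ValidationError(f"token {t.index}: head {t.head} out of [0, {n}]")
        if scheme == "relative":
            code = ROOT_CODE if t.head == 0 else f"{t.head - t.index:+d}"
        else:
            code = str(t.head)
        labels.append(SyntaxLabel(code, t.deprel))
    return labels


def decode_labels(labels: Sequence[SyntaxLabel], n: int, scheme: Scheme
                  ) -> tuple[list[int], list[str], list[bool]]:
    """Decode labels to (heads, deprels, repair_flags); never raises on content.

    A head that cannot be realized (unparseable code, out of [0, n], or equal
    to the token's own index) is attached to the root and flagged.
    """
    _check_scheme(scheme)
    if len(labels) != n:
        raise ValidationError(f"expected {n} labels, got {len(labels)}")
    heads: list[int] = []
    deprels: list[str] = []
    flags: list[bool] = []
    for i, lab in enumerate(labels, start=1):
        code = lab.head_code
        head: int | None
        if scheme == "relative" and code == ROOT_CODE:
            head = 0
        else:
            try:
                val = int(code)
                head = i + val if scheme == "relative" else val
            except (TypeError, ValueError):
                head = None
        bad = head is None or not (0 <= head <= n) or head == i
        heads.append(0 if bad else head)
        deprels.append(lab.deprel)
        flags.append(bad)
    return heads, deprels, flags


class LabelVocab:
    """Bidirectional label <-> dense id map with reserved PAD/UNK ids."""

    PAD = 0
    UNK = 1
    N_RESERVED = 2

    def __init__(self, labels: Iterable[str]):
        self._id2label = ["<PAD>", "<UNK>"]
        self._label2id: dict[str, int] = {}
        for lab in labels:
            if lab not in self._label2id:
                self._label2id[lab] = len(self._id2label)
                self._id2label.append(lab)

    def __len__(self) -> int:
        return len(self._id2label)

    def __contains__(self, label: str) -> bool:
        return label in self._label2id

    def id(self, label: str) -> int:
        return self._label2id.get(label, self.UNK)

    def label(self, i: int) -> str:
        return self._id2label[i]

    @property
    def labels(self) -> list[str]:
        return list(self._id2label[self.N_RESERVED:])

    @classmethod
    def from_counts(cls, counts: Counter) -> "LabelVocab":
        ordered = sorted(counts, key=lambda k: (-counts[k], k))
        return cls(ordered)


def build_label_vocab(corpus: Sequence[Sentence], scheme: Scheme, joint: bool
                      ) -> LabelVocab | tuple[LabelVocab, LabelVocab]:
    """Vocabulary over linearized labels, ordered by frequency then name.

    ``joint=True`` returns one vocabulary over (head_code, deprel) pairs;
    ``joint=False`` returns (head_code vocab, deprel vocab).
    """
    if not corpus:
        raise ValidationError("cannot build a label vocabulary from an empty corpus")
    if joint:
        counts: Counter = Counter()
        for sent in corpus:
            for lab in encode_dependencies(sent, scheme):
                counts[lab.joint()] += 1
        return LabelVocab.from_counts(counts)
    code_counts: Counter = Counter()
    rel_counts: Counter = Counter()
    for sent in corpus:
        for lab in encode_dependencies(sent, scheme):
            code_counts[lab.head_code] += 1
            rel_counts[lab.deprel] += 1
    return LabelVocab.from_counts(code_counts), LabelVocab.from_counts(rel_counts)
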