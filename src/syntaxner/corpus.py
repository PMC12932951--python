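"""Corpus containers and I/O.

Three on-disk formats are supported, all plain text:

* CoNLL-U (10 tab-separated columns) for dependency analyses.  Only
  ID/FORM/HEAD/DEPREL are interpreted; the remaining columns are carried
  opaquely so that ``write(read(f)) == f`` for the retained lines.
* Two-column BIO files (``token<TAB>tag``, blank line between sentences,
  ``-DOCSTART-`` lines skipped) — the CoNLL-2003 dialect used by the common
  biomedical NER benchmark distributions.
* A merged four-column TSV (FORM, HEAD, DEPREL, TAG) for joint NER+parse
  fixtures.

Entity spans use 0-based half-open token coordinates internally; the 1-based
CoNLL convention appears only at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from .errors import FormatError, ValidationError

_TAG_RE = re.compile(r"^(O|[BI]-\S+)$")

# CoNLL-U columns carried opaquely (LEMMA, UPOS, XPOS, FEATS, DEPS, MISC)
_N_EXTRA = 6
_DEFAULT_EXTRA = ("_",) * _N_EXTRA


def validate_tag(tag: str) -> str:
    if not _TAG_RE.match(tag):
        raise FormatError(f"malformed BIO tag: {tag!r}")
    return tag


@dataclass
class Token:
    """One token: 1-based index, surface form, optional head/deprel/BIO tag.

    ``head`` is an integer in [0, n] with 0 meaning the virtual root; it is
    None when no parse is attached.  ``extra`` carries the uninterpreted
    CoNLL-U columns for lossless round-tripping.
    """

    index: int
    form: str
    head: int | None = None
    deprel: str | None = None
    tag: str | None = None
    extra: tuple[str, ...] = _DEFAULT_EXTRA

    def __post_init__(self):
        if self.head is not None:
            if self.head == self.index:
                raise ValidationError(f"token {self.index}: head equals own index")
            if not self.deprel:
                raise ValidationError(f"token {self.index}: head set but deprel empty")
        if self.tag is not None:
            validate_tag(self.tag)


@dataclass
class Sentence:
    tokens: list[Token]
    comments: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.tokens)

    @property
    def forms(self) -> list[str]:
        return [t.form for t in self.tokens]

    @property
    def heads(self) -> list[int]:
        return [t.head for t in self.tokens]

    @property
    def deprels(self) -> list[str]:
        return [t.deprel for t in self.tokens]

    @property
    def tags(self) -> list[str]:
        return [t.tag for t in self.tokens]

    def __post_init__(self):
        for i, t in enumerate(self.tokens, start=1):
            if t.index != i:
                raise ValidationError(f"token indices must be 1..n; got {t.index} at position {i}")

    def validate_tree(self) -> None:
        """Check single root, heads in range, and acyclicity.

        Run on demand (parser output may be imperfect), never on construction.
        """
        n = self.n
        roots = 0
        for t in self.tokens:
            if t.head is None:
                raise ValidationError(f"token {t.index}: no head")
            if not (0 <= t.head <= n):
                raise ValidationError(f"token {t.index}: head {t.head} out of [0, {n}]")
            if t.head == 0:
                roots += 1
        if roots != 1:
            raise ValidationError(f"expected exactly one root, found {roots}")
        for t in self.tokens:
            seen = set()
            cur = t.index
            while cur != 0:
                if cur in seen:
                    raise ValidationError(f"cycle through token {t.index}")
                seen.add(cur)
                cur = self.tokens[cur - 1].head

    def is_projective(self) -> bool:
        arcs = [(min(t.index, t.head), max(t.index, t.head)) for t in self.tokens if t.head]
        for (a1, b1) in arcs:
            for (a2, b2) in arcs:
                if a1 < a2 < b1 < b2:
                    return False
        return True


@dataclass(frozen=True, order=True)
class EntitySpan:
    """(start, end-exclusive, type) in 0-based token coordinates."""

    start: int
    end: int
    type: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad span bounds ({self.start}, {self.end})")


# ---------------------------------------------------------------------------
# BIO tags <-> entity spans

def bio_to_spans(tags: list[str]) -> list[EntitySpan]:
    """Extract entities under the strict IOB2 reading.

    A span opens only with ``B-X`` and continues with consecutive ``I-X`` of
    the same type.  An ``I-X`` that does not continue a same-type run is an
    orphan and yields no span — the failure mode in which a system loses a
    whole entity by mistagging just its first token.
    """
    for t in tags:
        validate_tag(t)
    spans: list[EntitySpan] = []
    start, typ = None, None
    for i, t in enumerate(tags):
        if t.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(start, i, typ))
            start, typ = i, t[2:]
        elif t.startswith("I-") and start is not None and t[2:] == typ:
            continue
        else:  # O, or orphan/ type-changing I
            if start is not None:
                spans.append(EntitySpan(start, i, typ))
            start, typ = None, None
    if start is not None:
        spans.append(EntitySpan(start, len(tags), typ))
    return spans


def spans_to_bio(spans: Iterable[EntitySpan], n: int) -> list[str]:
    """Inverse of :func:`bio_to_spans` on its output."""
    tags = ["O"] * n
    occupied = [False] * n
    for s in sorted(spans):
        if s.end > n:
            raise ValidationError(f"span {s} exceeds sentence length {n}")
        if any(occupied[s.start:s.end]):
            raise ValidationError(f"overlapping span {s}")
        for i in range(s.start, s.end):
            occupied[i] = True
        tags[s.start] = f"B-{s.type}"
        for i in range(s.start + 1, s.end):
            tags[i] = f"I-{s.type}"
    return tags


# ---------------------------------------------------------------------------
# CoNLL-U

def read_conllu(stream: TextIO | Iterable[str]) -> list[Sentence]:
    """Parse CoNLL-U text into sentences.

    Comment lines (``#``) are retained verbatim; multiword-token ranges and
    empty-node decimal IDs are skipped.  HEAD must be an integer and IDs must
    run 1..n without gaps.
    """
    sentences: list[Sentence] = []
    tokens: list[Token] = []
    comments: list[str] = []

    def flush():
        nonlocal tokens, comments
        if tokens:
            sentences.append(Sentence(tokens, comments))
        tokens, comments = [], []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            comments.append(line)
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise FormatError(f"line {lineno}: expected 10 columns, got {len(cols)}")
        tok_id, form, head_s, deprel = cols[0], cols[1], cols[6], cols[7]
        if "-" in tok_id or "." in tok_id:  # multiword token range / empty node
            continue
        try:
            idx = int(tok_id)
        except ValueError as e:
            raise FormatError(f"line {lineno}: non-integer ID {tok_id!r}") from e
        if idx != len(tokens) + 1:
            raise FormatError(f"line {lineno}: ID sequence gap (expected {len(tokens) + 1}, got {idx})")
        try:
            head = int(head_s)
        except ValueError as e:
            raise FormatError(f"line {lineno}: non-integer HEAD {head_s!r}") from e
        extra = (cols[2], cols[3], cols[4], cols[5], cols[8], cols[9])
        tokens.append(Token(index=idx, form=form, head=head, deprel=deprel, extra=extra))
    flush()
    return sentences


def write_conllu(sentences: Iterable[Sentence], stream: TextIO) -> None:
    for sent in sentences:
        for c in sent.comments:
            stream.write(c + "\n")
        for t in sent.tokens:
            e = t.extra
            cols = [str(t.index), t.form, e[0], e[1], e[2], e[3],
                    str(t.head if t.head is not None else 0),
                    t.deprel or "dep", e[4], e[5]]
            stream.write("\t".join(cols) + "\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Two-column BIO files

def read_bio(stream: TextIO | Iterable[str]) -> list[Sentence]:
    sentences: list[Sentence] = []
    rows: list[tuple[str, str]] = []

    def flush():
        nonlocal rows
        if rows:
            toks = [Token(index=i, form=f, tag=validate_tag(g))
                    for i, (f, g) in enumerate(rows, start=1)]
            sentences.append(Sentence(toks))
        rows = []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("-DOCSTART-"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'token<TAB>tag', got {line!r}")
        rows.append((parts[0], parts[1]))
    flush()
    return sentences


def write_bio(sentences: Iterable[Sentence], stream: TextIO) -> None:
    for sent in sentences:
        for t in sent.tokens:
            if t.tag is None:
                raise ValidationError(f"token {t.index} has no BIO tag")
            stream.write(f"{t.form}\t{t.tag}\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Merged 4-column TSV (FORM, HEAD, DEPREL, TAG)

def read_merged_tsv(stream: TextIO | Iterable[str]) -> list[Sentence]:
    sentences: list[Sentence] = []
    rows: list[tuple[str, int, str, str]] = []

    def flush():
        nonlocal rows
        if rows:
            toks = [Token(index=i, form=f, head=h, deprel=d, tag=validate_tag(g))
                    for i, (f, h, d, g) in enumerate(rows, start=1)]
            sentences.append(Sentence(toks))
        rows = []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"line {lineno}: expected 4 columns, got {len(parts)}")
        form, head_s, deprel, tag = parts
        try:
            head = int(head_s)
        except ValueError as e:
            raise FormatError(f"line {lineno}: non-integer HEAD {head_s!r}") from e
        rows.append((form, head, deprel, tag))
    flush()
    return sentences


def write_merged_tsv(sentences: Iterable[Sentence], stream: TextIO) -> None:
    for sent in sentences:
        for t in sent.tokens:
            stream.write(f"{t.form}\t{t.head}\t{t.deprel}\t{t.tag}\n")
        stream.write("\n")


def iter_read(path, reader) -> list[Sentence]:
    with open(path, encoding="utf-8") as fh:
        return reader(fh)
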