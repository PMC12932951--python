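"""Scoring and error analysis.

The headline metric is strict entity-level micro precision/recall/F1: a
predicted entity counts as a true positive only when its span boundaries
AND its type both match a gold entity exactly.  A token-level variant (per
non-O token tag match) is provided separately, since the two can diverge
dramatically — a single missing B-tag loses a whole entity under the strict
metric while costing one token under the relaxed one.

``repair_bio`` is the postprocessor for exactly that failure mode: it
rewrites the first token of an orphan I-run to the matching B-tag, turning
otherwise-lost spans back into scoreable entities.

``analyze_errors`` stratifies mismatches the way NER error studies slice
them: by mistagged token form, by the token's gold dependency relation, by
distance to the syntactic head, and by a four-way categorization of entity
errors (span mismatch / type mismatch / false positive / false negative).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .corpus import EntitySpan, Sentence, bio_to_spans
from .errors import ValidationError

TagSeqs = list[list[str]]


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "PRF") -> "PRF":
        return PRF(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _check_aligned(gold: TagSeqs, pred: TagSeqs) -> None:
    if len(gold) != len(pred):
        raise ValidationError(f"sentence count mismatch: {len(gold)} vs {len(pred)}")
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValidationError(f"sentence {i}: length mismatch {len(g)} vs {len(p)}")


def evaluate_entities(gold: TagSeqs, pred: TagSeqs) -> PRF:
    """Strict entity-level micro PRF over a corpus of tag sequences."""
    _check_aligned(gold, pred)
    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        gs = set(bio_to_spans(g))
        ps = set(bio_to_spans(p))
        tp += len(gs & ps)
        fp += len(ps - gs)
        fn += len(gs - ps)
    return PRF(tp, fp, fn)


def evaluate_tokens(gold: TagSeqs, pred: TagSeqs) -> PRF:
    """Token-level variant: every non-O token counts individually."""
    _check_aligned(gold, pred)
    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        for gt, pt in zip(g, p):
            if pt != "O" and pt == gt:
                tp += 1
            else:
                if pt != "O":
                    fp += 1
                if gt != "O":
                    fn += 1
    return PRF(tp, fp, fn)


def repair_bio(tags: list[str]) -> list[str]:
    """Rewrite the first tag of every orphan I-run to B-<type>; idempotent."""
    out = list(tags)
    for i, t in enumerate(out):
        if t.startswith("I-"):
            prev = out[i - 1] if i > 0 else "O"
            if prev not in (f"B-{t[2:]}", f"I-{t[2:]}"):
                out[i] = "B-" + t[2:]
    return out


# ---------------------------------------------------------------------------
# Error analysis

CATEGORIES = ("span_mismatch", "type_mismatch", "false_positive", "false_negative")


@dataclass(frozen=True)
class MismatchRecord:
    sentence_id: int
    token_index: int  # 0-based
    gold_tag: str
    pred_tag: str
    form: str
    gold_deprel: str | None
    distance_to_head: int | None
    category: str


@dataclass
class ErrorReport:
    token_counts: Counter = field(default_factory=Counter)
    deprel_counts: Counter = field(default_factory=Counter)
    # distance d -> (mistagged tokens at d, all gold tokens at d)
    distance_bins: dict[int, tuple[int, int]] = field(default_factory=dict)
    category_counts: Counter = field(default_factory=Counter)
    mismatches: list[MismatchRecord] = field(default_factory=list)
    has_distance_curve: bool = True

    def distance_curve(self) -> dict[int, float]:
        return {d: (m / t if t else 0.0) for d, (m, t) in sorted(self.distance_bins.items())}

    def to_frames(self) -> dict[str, pd.DataFrame]:
        frames = {
            "tokens": pd.DataFrame(self.token_counts.most_common(),
                                   columns=["form", "count"]),
            "deprels": pd.DataFrame(self.deprel_counts.most_common(),
                                    columns=["deprel", "count"]),
            "categories": pd.DataFrame(sorted(self.category_counts.items()),
                                       columns=["category", "count"]),
        }
        if self.has_distance_curve:
            frames["distance"] = pd.DataFrame(
                [(d, m, t, (m / t if t else 0.0))
                 for d, (m, t) in sorted(self.distance_bins.items())],
                columns=["distance", "mistagged", "total", "error_rate"])
        return frames


def _overlaps(a: EntitySpan, b: EntitySpan) -> bool:
    return a.start < b.end and b.start < a.end


def _categorize(gold_spans: list[EntitySpan], pred_spans: list[EntitySpan]) -> dict:
    """Four-way categorization of non-exact entities in one sentence.

    Priority for a missed gold span: a prediction with identical boundaries
    but different type is a type mismatch; any overlapping prediction is a
    span mismatch; no overlap at all is a false negative.  Predicted spans
    overlapping no gold span are false positives.
    """
    cats = Counter()
    gold_cat: dict[EntitySpan, str] = {}
    pred_cat: dict[EntitySpan, str] = {}
    exact = set(gold_spans) & set(pred_spans)
    for gsp in gold_spans:
        if gsp in exact:
            continue
        same_bounds = [p for p in pred_spans if (p.start, p.end) == (gsp.start, gsp.end)]
        overlapping = [p for p in pred_spans if _overlaps(gsp, p)]
        if same_bounds:
            cat = "type_mismatch"
        elif overlapping:
            cat = "span_mismatch"
        else:
            cat = "false_negative"
        gold_cat[gsp] = cat
        cats[cat] += 1
    for psp in pred_spans:
        if psp in exact:
            continue
        if not any(_overlaps(psp, g) for g in gold_spans):
            pred_cat[psp] = "false_positive"
            cats["false_positive"] += 1
    return {"counts": cats, "gold": gold_cat, "pred": pred_cat}


def _token_category(i: int, cat_info: dict, gold_spans, pred_spans) -> str:
    for gsp, cat in cat_info["gold"].items():
        if gsp.start <= i < gsp.end:
            return cat
    for psp, cat in cat_info["pred"].items():
        if psp.start <= i < psp.end:
            return cat
    # mismatched token inside an exactly-matched span cannot occur; outside
    # all spans the disagreement is a stray prediction artifact
    return "span_mismatch"


def analyze_errors(gold_corpus: list[Sentence], pred_tags: TagSeqs) -> ErrorReport:
    """Aggregate mismatch statistics between a gold corpus and predictions.

    The distance-to-head curve needs trees on the gold corpus; without them
    it is omitted with a warning and the remaining tables are produced.
    Root-attached tokens are assigned distance 0 (their own bin); all other
    tokens have distance |index - head| >= 1.
    """
    gold = [s.tags for s in gold_corpus]
    _check_aligned(gold, pred_tags)
    have_trees = all(t.head is not None for s in gold_corpus for t in s.tokens)
    if not have_trees:
        warnings.warn("gold corpus lacks dependency trees; distance curve omitted")

    report = ErrorReport(has_distance_curve=have_trees)
    for sid, (sent, pred) in enumerate(zip(gold_corpus, pred_tags)):
        gold_spans = bio_to_spans(sent.tags)
        pred_spans = bio_to_spans(pred)
        cat_info = _categorize(gold_spans, pred_spans)
        report.category_counts.update(cat_info["counts"])
        for i, (tok, pt) in enumerate(zip(sent.tokens, pred)):
            dist = None
            if have_trees:
                dist = 0 if tok.head == 0 else abs(tok.index - tok.head)
                m, t = report.distance_bins.get(dist, (0, 0))
                report.distance_bins[dist] = (m + (tok.tag != pt), t + 1)
            if tok.tag != pt:
                report.token_counts[tok.form] += 1
                if tok.deprel is not None:
                    report.deprel_counts[tok.deprel] += 1
                report.mismatches.append(MismatchRecord(
                    sentence_id=sid, token_index=i, gold_tag=tok.tag, pred_tag=pt,
                    form=tok.form, gold_deprel=tok.deprel, distance_to_head=dist,
                    category=_token_category(i, cat_info, gold_spans, pred_spans)))
    return report
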