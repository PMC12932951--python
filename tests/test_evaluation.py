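import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntaxner.corpus import Sentence, Token
from syntaxner.errors import ValidationError
from syntaxner.evaluation import (PRF, analyze_errors, evaluate_entities,
                                  evaluate_tokens, repair_bio)

# ---------------------------------------------------------------------------
# Independent brute-force oracle: a second, structurally different span
# extractor plus explicit set intersection.


def _oracle_spans(tags):
    spans = set()
    i = 0
    while i < len(tags):
        if tags[i].startswith("B-"):
            typ = tags[i][2:]
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{typ}":
                j += 1
            spans.add((i, j, typ))
            i = j
        else:
            i += 1
    return spans


def _oracle_prf(gold_seqs, pred_seqs):
    tp = fp = fn = 0
    for g, p in zip(gold_seqs, pred_seqs):
        gs, ps = _oracle_spans(g), _oracle_spans(p)
        tp += len(gs & ps)
        fp += len(ps - gs)
        fn += len(gs - ps)
    return tp, fp, fn


def _random_tags(rng, n):
    menu = ["O", "B-A", "I-A", "B-B", "I-B"]
    return [menu[int(rng.integers(5))] for _ in range(n)]


def test_exact_match_scores_one():
    prf = evaluate_entities([["B-D", "I-D", "O"]], [["B-D", "I-D", "O"]])
    assert prf.precision == prf.recall == prf.f1 == 1.0


def test_partial_span_scores_zero():
    """A boundary error loses the whole entity under the strict metric."""
    prf = evaluate_entities([["B-D", "I-D"]], [["B-D", "O"]])
    assert (prf.tp, prf.fp, prf.fn) == (0, 1, 1)
    assert prf.f1 == 0.0


def test_type_error_scores_zero():
    prf = evaluate_entities([["B-D", "I-D"]], [["B-X", "I-X"]])
    assert (prf.tp, prf.fp, prf.fn) == (0, 1, 1)


def test_strict_prf_matches_bruteforce_oracle(rng):
    """10,000 random gold/pred pairs agree exactly with the set-intersection
    oracle (lengths <= 6, two entity types)."""
    for _ in range(10_000):
        n = int(rng.integers(1, 7))
        g, p = _random_tags(rng, n), _random_tags(rng, n)
        prf = evaluate_entities([g], [p])
        assert (prf.tp, prf.fp, prf.fn) == _oracle_prf([g], [p])


def test_micro_average_consistency(rng):
    """Summed per-sentence counts equal the single concatenated-corpus count."""
    gold = [_random_tags(rng, int(rng.integers(1, 7))) for _ in range(50)]
    pred = [_random_tags(rng, len(g)) for g in gold]
    whole = evaluate_entities(gold, pred)
    summed = PRF(0, 0, 0)
    for g, p in zip(gold, pred):
        summed = summed + evaluate_entities([g], [p])
    assert (whole.tp, whole.fp, whole.fn) == (summed.tp, summed.fp, summed.fn)


def test_token_level_variant():
    prf = evaluate_tokens([["B-D", "I-D", "O"]], [["B-D", "O", "O"]])
    assert (prf.tp, prf.fp, prf.fn) == (1, 0, 1)


def test_length_mismatch_rejected():
    with pytest.raises(ValidationError):
        evaluate_entities([["O", "O"]], [["O"]])
    with pytest.raises(ValidationError):
        evaluate_entities([["O"], ["O"]], [["O"]])


def test_empty_prediction_degenerate_counts():
    prf = evaluate_entities([[("O")]], [["O"]])
    assert prf.precision == 0.0 and prf.recall == 0.0 and prf.f1 == 0.0


# ---------------------------------------------------------------------------
# B-tag repair


@pytest.mark.parametrize("tags,expected", [
    (["O", "I-D", "I-D"], ["O", "B-D", "I-D"]),
    (["B-D", "I-D"], ["B-D", "I-D"]),
    (["I-D"], ["B-D"]),
    (["B-A", "I-B", "I-B"], ["B-A", "B-B", "I-B"]),   # type change opens a new run
    (["O"], ["O"]),
])
def test_repair_bio(tags, expected):
    assert repair_bio(tags) == expected


@given(st.lists(st.sampled_from(["O", "B-A", "I-A", "B-B", "I-B"]), min_size=1, max_size=12))
@settings(max_examples=300, deadline=None)
def test_repair_idempotent(tags):
    once = repair_bio(tags)
    assert repair_bio(once) == once


def test_repair_only_adds_spans_so_recall_never_drops(rng):
    """Repair touches only orphan I tokens, which contribute no entity under
    strict extraction: every previously extracted span survives, so against
    any gold the entity-level recall cannot drop.  (Token-level accuracy CAN
    drop — an orphan I that happens to match a gold I becomes a B — so only
    the span-level monotonicity is asserted.)"""
    from syntaxner.corpus import bio_to_spans, spans_to_bio
    from test_corpus_io import _random_disjoint_spans

    for _ in range(500):
        n = int(rng.integers(1, 10))
        gold = spans_to_bio(_random_disjoint_spans(rng, n), n)
        pred = _random_tags(rng, n)
        fixed = repair_bio(pred)
        assert set(bio_to_spans(pred)) <= set(bio_to_spans(fixed))
        before = evaluate_entities([gold], [pred])
        after = evaluate_entities([gold], [fixed])
        assert after.recall >= before.recall


# ---------------------------------------------------------------------------
# Error analysis


def _sent(forms, heads, deprels, tags):
    return Sentence([Token(index=i, form=f, head=h, deprel=d, tag=t)
                     for i, (f, h, d, t) in
                     enumerate(zip(forms, heads, deprels, tags), start=1)])


def test_perfect_predictions_give_empty_report():
    s = _sent(["a", "b"], [2, 0], ["nsubj", "root"], ["B-D", "O"])
    rep = analyze_errors([s], [["B-D", "O"]])
    assert not rep.token_counts and not rep.deprel_counts and not rep.category_counts
    assert all(rate == 0.0 for rate in rep.distance_curve().values())


def test_planted_mistags_top_token_table():
    """Three planted mistags on 'of' put it at the top of the token table."""
    sents, preds = [], []
    for k in range(5):
        s = _sent(["risk", "of", "fever"], [0, 1, 2], ["root", "prep", "pobj"],
                  ["O", "O", "B-D"])
        tags = ["O", "O", "B-D"]
        if k < 3:
            tags = ["O", "B-D", "I-D"]  # mistag 'of' (and extend the span)
        sents.append(s)
        preds.append(tags)
    rep = analyze_errors(sents, preds)
    assert rep.token_counts.most_common(1) == [("of", 3)]
    assert rep.deprel_counts["prep"] == 3


def test_distance_curve_normalized():
    """One mistag among ten tokens at distance 3 gives rate 0.1 at d=3."""
    sents, preds = [], []
    for k in range(10):
        # token 1 attaches to token 4: distance 3
        s = _sent(["x", "f", "g", "v"], [4, 4, 4, 0],
                  ["obj", "compound", "compound", "root"],
                  ["B-D", "O", "O", "O"])
        pred = ["B-D", "O", "O", "O"] if k else ["O", "O", "O", "O"]
        sents.append(s)
        preds.append(pred)
    rep = analyze_errors(sents, preds)
    curve = rep.distance_curve()
    assert curve[3] == pytest.approx(0.1)


def test_root_tokens_binned_at_distance_zero():
    s = _sent(["v"], [0], ["root"], ["B-D"])
    rep = analyze_errors([s], [["O"]])
    assert rep.distance_bins[0] == (1, 1)


def test_missing_trees_omit_distance_curve():
    s = Sentence([Token(1, "a", tag="B-D"), Token(2, "b", tag="O")])
    with pytest.warns(UserWarning, match="distance"):
        rep = analyze_errors([s], [["O", "O"]])
    assert not rep.has_distance_curve
    assert rep.token_counts["a"] == 1  # rest of the report still produced


@pytest.mark.parametrize("pred,category", [
    (["B-X", "I-X", "O"], "type_mismatch"),     # same bounds, wrong type
    (["B-D", "O", "O"], "span_mismatch"),       # overlapping, unequal
    (["O", "O", "O"], "false_negative"),        # no overlap at all
    (["B-D", "I-D", "B-D"], "false_positive"),  # extra disjoint prediction
])
def test_entity_error_categories(pred, category):
    s = _sent(["a", "b", "c"], [2, 0, 2], ["amod", "root", "punct"],
              ["B-D", "I-D", "O"])
    rep = analyze_errors([s], [pred])
    assert rep.category_counts[category] >= 1


def test_mismatch_records_carry_syntax_context():
    s = _sent(["a", "b"], [2, 0], ["amod", "root"], ["B-D", "O"])
    rep = analyze_errors([s], [["O", "O"]])
    (rec,) = rep.mismatches
    assert rec.form == "a" and rec.gold_deprel == "amod"
    assert rec.distance_to_head == 1 and rec.category == "false_negative"
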