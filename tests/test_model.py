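import numpy as np
import pytest

import syntaxner.graph
import syntaxner.label_embed
from syntaxner.corpus import Sentence, Token
from syntaxner.errors import AlignmentError, ValidationError
from syntaxner.evaluation import evaluate_entities
from syntaxner.model import (ModelConfig, align_subwords, build_model, load_model,
                             model_forward, predict_tags, save_model, train_model,
                             train_multitask)
from syntaxner.nn import autodiff as ad
from syntaxner.simulate import GenConfig, generate_corpus, generate_splits

FAST = dict(hidden=16, head_dim=8, rel_dim=8, enc_heads=2, rgat_heads=2, rgat_layers=1)


@pytest.fixture(scope="module")
def corpus():
    tr, dv, te = generate_splits(GenConfig(n_sentences=1, seed=99), 24, 8, 8)
    return tr, dv, te


# ---------------------------------------------------------------------------
# Subword alignment


def test_align_first_piece():
    vecs = np.arange(12).reshape(6, 2)
    out = align_subwords([["hea", "##da", "##che"], ["hurts"]],
                         vecs, n_special_prefix=1, n_special_suffix=1)
    assert np.array_equal(out, vecs[[1, 4]])


def test_align_identity_when_unsplit():
    vecs = np.arange(8).reshape(4, 2)
    assert np.array_equal(align_subwords([1, 1, 1, 1], vecs), vecs)


def test_align_zero_pieces_named():
    with pytest.raises(AlignmentError, match="position 1"):
        align_subwords([["a"], []], np.ones((1, 2)))


def test_align_count_mismatch():
    with pytest.raises(AlignmentError):
        align_subwords([2, 2], np.ones((3, 4)))


# ---------------------------------------------------------------------------
# Forward contracts


@pytest.mark.parametrize("mode", ["none", "graph", "seqlab"])
def test_rows_are_distributions(corpus, mode):
    tr, _, _ = corpus
    cfg = ModelConfig(syntax_mode=mode, seed=1, **FAST)
    model = build_model(tr, cfg, np.random.default_rng(1))
    probs, alpha = model_forward(model, tr[0])
    assert probs.shape[0] == tr[0].n
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    if mode == "none":
        assert alpha is None
    else:
        assert alpha.shape == (tr[0].n, 2)
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)


def test_eval_forward_bitwise_repeatable(corpus):
    tr, _, _ = corpus
    cfg = ModelConfig(syntax_mode="graph", seed=1, **FAST)
    model = build_model(tr, cfg, np.random.default_rng(5))
    p1, a1 = model_forward(model, tr[0])
    p2, a2 = model_forward(model, tr[0])
    assert np.array_equal(p1, p2) and np.array_equal(a1, a2)


def test_forced_contextual_gate_equals_baseline(corpus):
    """alpha forced to (1,0) reproduces the baseline probabilities exactly
    given identical encoder and classifier parameters."""
    tr, _, _ = corpus
    syn = build_model(tr, ModelConfig(syntax_mode="graph", seed=1, **FAST),
                      np.random.default_rng(2))
    base = build_model(tr, ModelConfig(syntax_mode="none", seed=1, **FAST),
                       np.random.default_rng(3))
    shared = {k: v for k, v in syn.state_dict().items()
              if k.startswith(("encoder.", "classifier."))}
    state = base.state_dict()
    state.update(shared)
    base.load_state_dict(state)
    for s in tr[:5]:
        forced, _ = model_forward(syn, s, force_alpha=(1.0, 0.0))
        plain, _ = model_forward(base, s)
        assert np.array_equal(forced, plain)


def test_baseline_reaches_no_syntax_code(corpus, monkeypatch):
    """In syntax_mode=none no graph or label-embedding code is reachable."""
    tr, dv, _ = corpus

    def boom(*a, **k):
        raise AssertionError("syntax pathway reached in baseline mode")

    import syntaxner.model
    monkeypatch.setattr(syntaxner.graph.RGATEncoder, "__call__", boom)
    monkeypatch.setattr(syntaxner.label_embed.SyntaxLabelEmbedder, "forward", boom)
    monkeypatch.setattr(syntaxner.graph, "build_graph", boom)
    monkeypatch.setattr(syntaxner.model, "build_graph", boom)
    monkeypatch.setattr(syntaxner.model, "encode_dependencies", boom)
    cfg = ModelConfig(syntax_mode="none", max_epochs=1, seed=1, **FAST)
    res = train_model(tr, dv, cfg)
    model_forward(res.model, tr[0])


def test_parse_required_when_syntactic(corpus):
    tr, _, _ = corpus
    cfg = ModelConfig(syntax_mode="graph", seed=1, **FAST)
    model = build_model(tr, cfg, np.random.default_rng(4))
    bare = Sentence([Token(1, "rash"), Token(2, ".")])
    with pytest.raises(ValidationError):
        model_forward(model, bare)


def test_padded_and_unpadded_loss_identical(corpus):
    """Masked attention + masked loss make padding a no-op (within 1e-6)."""
    tr, _, _ = corpus
    cfg = ModelConfig(syntax_mode="none", seed=1, **FAST)
    model = build_model(tr, cfg, np.random.default_rng(6))
    for s in tr[:6]:
        tags = model.tag_vocab.ids(s.tags)
        plain, _ = model.logits(s)
        padded, _ = model.logits(s, pad_to=s.n + 7)
        l1 = ad.cross_entropy(plain, tags).data
        l2 = ad.cross_entropy(padded, tags).data
        assert abs(float(l1) - float(l2)) < 1e-6


def test_truncation_warns_and_pads_O(corpus):
    tr, _, _ = corpus
    cfg = ModelConfig(syntax_mode="none", seed=1, max_len=4, **FAST)
    model = build_model(tr, cfg, np.random.default_rng(7))
    long_sent = next(s for s in tr if s.n > 4)
    with pytest.warns(UserWarning, match="truncated"):
        (tags,) = predict_tags(model, [long_sent])
    assert len(tags) == long_sent.n
    assert all(t == "O" for t in tags[4:])


# ---------------------------------------------------------------------------
# Training


def test_loss_descends(corpus):
    tr, dv, _ = corpus
    cfg = ModelConfig(syntax_mode="none", max_epochs=6, patience=100, seed=11, **FAST)
    res = train_model(tr, dv, cfg)
    assert res.log[5]["train_loss"] < res.log[0]["train_loss"]


def test_training_reproducible(corpus):
    tr, dv, _ = corpus
    cfg = ModelConfig(syntax_mode="graph", max_epochs=3, patience=100, seed=21, **FAST)
    r1 = train_model(tr, dv, cfg)
    r2 = train_model(tr, dv, cfg)
    assert [e["dev_f1"] for e in r1.log] == [e["dev_f1"] for e in r2.log]
    assert [e["train_loss"] for e in r1.log] == [e["train_loss"] for e in r2.log]


def test_unseen_dev_label_rejected_before_training(corpus):
    tr, _, _ = corpus
    weird = Sentence([Token(1, "x", 0, "root", tag="B-Zebra")])
    cfg = ModelConfig(syntax_mode="none", max_epochs=1, seed=1, **FAST)
    with pytest.raises(ValidationError, match="Zebra"):
        train_model(tr, [weird], cfg)


def test_missing_trees_rejected_in_syntax_mode():
    plain = [Sentence([Token(1, "a", tag="O"), Token(2, "b", tag="O")])]
    cfg = ModelConfig(syntax_mode="graph", max_epochs=1, seed=1, **FAST)
    with pytest.raises(ValidationError):
        train_model(plain, plain, cfg)


def test_deprel_perturbation_changes_loss(corpus):
    """Syntax is not dead weight: flipping one deprel moves the prediction."""
    tr, _, _ = corpus
    cfg = ModelConfig(syntax_mode="graph", max_epochs=3, patience=100, seed=31, **FAST)
    res = train_model(tr, tr[:4], cfg)
    sent = next(s for s in tr if any(t.deprel == "obj" for t in s.tokens))
    probs, _ = model_forward(res.model, sent)
    toks = [Token(t.index, t.form, t.head,
                  "nsubj" if t.deprel == "obj" else t.deprel, tag=t.tag)
            for t in sent.tokens]
    probs2, _ = model_forward(res.model, Sentence(toks))
    assert not np.allclose(probs, probs2)


def test_predict_preserves_order_and_lengths(corpus):
    tr, dv, _ = corpus
    cfg = ModelConfig(syntax_mode="none", max_epochs=1, seed=1, **FAST)
    res = train_model(tr, dv, cfg)
    preds = predict_tags(res.model, dv)
    assert [len(p) for p in preds] == [s.n for s in dv]


def test_predict_repair_applies_postprocessor(corpus):
    tr, dv, _ = corpus
    cfg = ModelConfig(syntax_mode="none", max_epochs=1, seed=1, **FAST)
    res = train_model(tr, dv, cfg)
    from syntaxner.evaluation import repair_bio
    raw = predict_tags(res.model, dv, repair=False)
    fixed = predict_tags(res.model, dv, repair=True)
    assert fixed == [repair_bio(t) for t in raw]


def test_save_load_roundtrip(tmp_path, corpus):
    tr, dv, _ = corpus
    cfg = ModelConfig(syntax_mode="seqlab", max_epochs=2, seed=41, **FAST)
    res = train_model(tr, dv, cfg)
    save_model(res, tmp_path / "m")
    back = load_model(tmp_path / "m")
    assert predict_tags(back, dv) == predict_tags(res.model, dv)


# ---------------------------------------------------------------------------
# Multi-task


def test_mtl_zero_parse_weight_matches_single_task(corpus):
    tr, dv, _ = corpus
    kw = dict(max_epochs=4, patience=100, seed=51, **FAST)
    single = train_model(tr, dv, ModelConfig(syntax_mode="none", **kw))
    multi = train_multitask(tr, dv, ModelConfig(syntax_mode="none", w_parse=0.0, **kw))
    assert [e["dev_f1"] for e in single.log] == [e["dev_f1"] for e in multi.log]
    assert [e["train_loss"] for e in single.log] == [e["train_loss"] for e in multi.log]


def test_mtl_losses_logged_and_finite(corpus):
    tr, dv, _ = corpus
    cfg = ModelConfig(max_epochs=3, patience=100, seed=61, **FAST)
    res = train_multitask(tr, dv, cfg)
    for entry in res.log:
        assert np.isfinite(entry["train_loss"]) and np.isfinite(entry["parse_loss"])


def test_mtl_requires_trees():
    plain = [Sentence([Token(1, "a", tag="O")])]
    with pytest.raises(ValidationError):
        train_multitask(plain, plain, ModelConfig(max_epochs=1, seed=1, **FAST))
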