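"""Model assembly, training and prediction.

The network has two pathways per token.  The contextual pathway is an
encoder satisfying a small adapter contract — any callable mapping the
sentence's words to an n x H matrix.  The implementation shipped here is a
compact trainable self-attention encoder (learned word + position
embeddings, multi-head attention, feedforward block) sized for CPU-scale
experiments; a pretrained transformer backbone satisfies the same contract
via :func:`align_subwords`.  The syntactic pathway is selected by
``syntax_mode``:

* ``graph``  — a relational graph attention network over the typed
  dependency graph (:mod:`syntaxner.graph`),
* ``seqlab`` — embeddings of the linearized per-token parse labels
  (:mod:`syntaxner.label_embed`),
* ``none``   — the pure fine-tuning baseline; no syntax computation is
  reachable and the fusion gate is bypassed entirely.

Pathways are merged by the token-level fusion gate, dropped out, and
classified into BIO tags by a linear softmax layer.  The multi-task variant
drops the gate: NER and sequence-labelling parsing share the encoder and
own separate linear decoders, with total loss w_ner*L_ner + w_parse*L_parse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Sentence
from .errors import AlignmentError, ValidationError
from .evaluation import evaluate_entities, repair_bio
from .fusion import FusionGate
from .graph import RGATEncoder, RelationVocab, build_graph
from .label_embed import SyntaxLabelEmbedder
from .linearize import LabelVocab, build_label_vocab, encode_dependencies
from .nn import AdamW, Embedding, Linear, Module, glorot
from .nn import autodiff as ad

SYNTAX_MODES = ("none", "graph", "seqlab")


@dataclass
class ModelConfig:
    syntax_mode: str = "none"
    scheme: str = "absolute"
    hidden: int = 32
    dropout: float = 0.1
    enc_layers: int = 1
    enc_heads: int = 4
    max_len: int = 64
    rgat_layers: int = 2
    rgat_heads: int = 4
    rgat_residual: bool = False
    head_dim: int = 64
    rel_dim: int = 32
    lr: float = 3e-3
    weight_decay: float = 0.01
    batch_size: int = 16
    max_epochs: int = 20
    patience: int = 3
    seed: int = 0
    mtl: bool = False
    w_ner: float = 1.0
    w_parse: float = 1.0
    mtl_joint: bool = True

    def __post_init__(self):
        if self.syntax_mode not in SYNTAX_MODES:
            raise ValidationError(f"syntax_mode must be one of {SYNTAX_MODES}")
        if self.scheme not in ("relative", "absolute"):
            raise ValidationError("scheme must be 'relative' or 'absolute'")


# ---------------------------------------------------------------------------
# Vocabularies

class WordVocab:
    PAD = 0
    UNK = 1

    def __init__(self, forms):
        self._id2w = ["<PAD>", "<UNK>"]
        self._w2id: dict[str, int] = {}
        for w in forms:
            if w not in self._w2id:
                self._w2id[w] = len(self._id2w)
                self._id2w.append(w)

    def __len__(self):
        return len(self._id2w)

    def ids(self, forms: Sequence[str]) -> np.ndarray:
        return np.array([self._w2id.get(w, self.UNK) for w in forms], dtype=np.intp)

    @property
    def words(self) -> list[str]:
        return list(self._id2w[2:])

    @classmethod
    def from_corpus(cls, corpus: Sequence[Sentence]) -> "WordVocab":
        seen, ordered = set(), []
        for s in corpus:
            for t in s.tokens:
                if t.form not in seen:
                    seen.add(t.form)
                    ordered.append(t.form)
        return cls(ordered)


class TagVocab:
    """Dense BIO tag ids, lexicographically ordered (stable argmax ties)."""

    def __init__(self, tags):
        self.tags = sorted(set(tags))
        self._t2id = {t: i for i, t in enumerate(self.tags)}

    def __len__(self):
        return len(self.tags)

    def id(self, tag: str) -> int:
        if tag not in self._t2id:
            raise ValidationError(f"tag {tag!r} not in training label set {self.tags}")
        return self._t2id[tag]

    def ids(self, tags: Sequence[str]) -> np.ndarray:
        return np.array([self.id(t) for t in tags], dtype=np.intp)

    def tag(self, i: int) -> str:
        return self.tags[i]


# ---------------------------------------------------------------------------
# Subword alignment (contract for pretrained-backbone adapters)

def align_subwords(pieces_per_word: Sequence[Sequence[str]] | Sequence[int],
                   piece_vectors: np.ndarray,
                   n_special_prefix: int = 0,
                   n_special_suffix: int = 0) -> np.ndarray:
    """First-piece pooling: each word's vector is its first subword's vector.

    ``pieces_per_word`` gives, per word, its subword pieces (or just their
    count); ``piece_vectors`` holds one row per piece including any special
    boundary pieces, which are excluded via the prefix/suffix counts.
    """
    counts = [len(p) if not isinstance(p, int) else p for p in pieces_per_word]
    for w, c in enumerate(counts):
        if c < 1:
            raise AlignmentError(f"word at position {w} has zero subword pieces")
    body = piece_vectors[n_special_prefix: piece_vectors.shape[0] - n_special_suffix or None]
    if sum(counts) != body.shape[0]:
        raise AlignmentError(f"piece count mismatch: {sum(counts)} vs {body.shape[0]} rows")
    firsts = np.cumsum([0] + counts[:-1])
    return body[firsts]


# ---------------------------------------------------------------------------
# Tiny self-attention encoder

class SelfAttentionBlock(Module):
    def __init__(self, rng, hidden: int, heads: int):
        if hidden % heads:
            raise ValidationError(f"hidden {hidden} not divisible by {heads} heads")
        self.heads = heads
        self.d_head = hidden // heads
        self.Wq = Linear(rng, hidden, hidden)
        self.Wk = Linear(rng, hidden, hidden)
        self.Wv = Linear(rng, hidden, hidden)
        self.Wo = Linear(rng, hidden, hidden)
        self.ff1 = Linear(rng, hidden, hidden)
        self.ff2 = Linear(rng, hidden, hidden)

    def __call__(self, x: ad.Tensor, key_mask: np.ndarray | None = None) -> ad.Tensor:
        n = x.shape[0]
        K, dh = self.heads, self.d_head

        def split(t):  # (n, H) -> (K, n, dh)
            return ad.transpose(ad.reshape(t, (n, K, dh)), (1, 0, 2))

        q, k, v = split(self.Wq(x)), split(self.Wk(x)), split(self.Wv(x))
        scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 2, 1))), 1.0 / np.sqrt(dh))
        if key_mask is not None:  # False key positions are unattendable padding
            bias = np.where(key_mask, 0.0, -1e30)[None, None, :]
            scores = ad.add(scores, ad.constant(np.broadcast_to(bias, (K, n, n))))
        att = ad.softmax(scores, axis=-1)
        ctx = ad.reshape(ad.transpose(ad.matmul(att, v), (1, 0, 2)), (n, K * dh))
        x = ad.tanh(ad.add(x, self.Wo(ctx)))
        return ad.tanh(ad.add(x, self.ff2(ad.tanh(self.ff1(x)))))


class TinyEncoder(Module):
    """Randomly initialized trainable contextual encoder (adapter impl b)."""

    def __init__(self, rng, vocab: WordVocab, hidden: int, layers: int,
                 heads: int, max_len: int):
        self.vocab = vocab
        self.hidden = hidden
        self.max_len = max_len
        self.word_emb = Embedding(rng, len(vocab), hidden)
        self.pos_emb = Embedding(rng, max_len, hidden)
        self.blocks = [SelfAttentionBlock(rng, hidden, heads) for _ in range(layers)]

    def __call__(self, word_ids: np.ndarray, key_mask: np.ndarray | None = None) -> ad.Tensor:
        n = len(word_ids)
        x = ad.add(self.word_emb(word_ids), self.pos_emb(np.arange(n)))
        for blk in self.blocks:
            x = blk(x, key_mask)
        return x


# ---------------------------------------------------------------------------
# Full model

def _slice_rows(t: ad.Tensor, n: int) -> ad.Tensor:
    return ad.gather_rows(t, np.arange(n))


class NERModel(Module):
    def __init__(self, config: ModelConfig, word_vocab: WordVocab, tag_vocab: TagVocab,
                 rng: np.random.Generator,
                 relations: RelationVocab | None = None,
                 head_vocab: LabelVocab | None = None,
                 rel_vocab: LabelVocab | None = None):
        cfg = config
        self.config = cfg
        self.tag_vocab = tag_vocab
        self.encoder = TinyEncoder(rng, word_vocab, cfg.hidden, cfg.enc_layers,
                                   cfg.enc_heads, cfg.max_len)
        self.rgat = None
        self.labemb = None
        self.gate = None
        self.relations = relations
        if cfg.syntax_mode == "graph":
            if relations is None:
                raise ValidationError("graph mode needs a relation vocabulary")
            self.rgat = RGATEncoder(rng, len(relations), cfg.hidden, cfg.hidden,
                                    layers=cfg.rgat_layers, heads=cfg.rgat_heads,
                                    residual=cfg.rgat_residual)
        elif cfg.syntax_mode == "seqlab":
            if head_vocab is None or rel_vocab is None:
                raise ValidationError("seqlab mode needs head/deprel label vocabularies")
            self.labemb = SyntaxLabelEmbedder(rng, head_vocab, rel_vocab, cfg.hidden,
                                              cfg.head_dim, cfg.rel_dim)
        if cfg.syntax_mode != "none":
            self.gate = FusionGate(rng, cfg.hidden)
        self.classifier = Linear(rng, cfg.hidden, len(tag_vocab))

    # -- forward ------------------------------------------------------------

    def _check_parse(self, sentence: Sentence):
        if any(t.head is None for t in sentence.tokens):
            raise ValidationError("syntax mode requires a dependency parse on every sentence")

    def features(self, sentence: Sentence, train_mode: bool = False,
                 drop_rng: np.random.Generator | None = None,
                 force_alpha: tuple[float, float] | None = None,
                 pad_to: int | None = None) -> tuple[ad.Tensor, ad.Tensor | None]:
        """Final per-token representation (n, H) and gate weights (or None)."""
        cfg = self.config
        n = min(sentence.n, cfg.max_len)
        if sentence.n > cfg.max_len:
            warnings.warn(f"sentence of length {sentence.n} truncated to {cfg.max_len}")
        forms = sentence.forms[:n]
        ids = self.encoder.vocab.ids(forms)
        key_mask = None
        if pad_to is not None and pad_to > n:
            ids = np.concatenate([ids, np.full(pad_to - n, WordVocab.PAD, dtype=np.intp)])
            key_mask = np.arange(pad_to) < n
        h = self.encoder(ids, key_mask)
        if pad_to is not None and pad_to > n:
            h = _slice_rows(h, n)
        alpha = None
        if cfg.syntax_mode == "none":
            feats = h
        else:
            self._check_parse(sentence)
            if cfg.syntax_mode == "graph":
                graph = build_graph(_truncated(sentence, n), self.relations)
                g = self.rgat(h, graph)
            else:
                labels = encode_dependencies(_truncated(sentence, n), cfg.scheme)
                g = self.labemb.forward(labels)
            feats, alpha = self.gate.forward(h, g, force_alpha=force_alpha)
        if train_mode and cfg.dropout > 0:
            if drop_rng is None:
                raise ValidationError("training-mode dropout needs a generator")
            keep = (drop_rng.random(feats.shape) >= cfg.dropout) / (1 - cfg.dropout)
            feats = ad.mul(feats, ad.constant(keep))
        return feats, alpha

    def logits(self, sentence: Sentence, **kw) -> tuple[ad.Tensor, ad.Tensor | None]:
        feats, alpha = self.features(sentence, **kw)
        return self.classifier(feats), alpha


def _truncated(sentence: Sentence, n: int) -> Sentence:
    """Clip to the encoder window; heads beyond it reattach to the root."""
    if sentence.n <= n:
        return sentence
    toks = [replace(t, head=(t.head if t.head is not None and t.head <= n else 0),
                    deprel=(t.deprel if (t.head is not None and t.head <= n) else "root"))
            for t in sentence.tokens[:n]]
    return Sentence(toks)


def model_forward(model: NERModel, sentence: Sentence,
                  force_alpha: tuple[float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray | None]:
    """Evaluation-mode forward: (n x |labels|) probabilities, gate weights.

    Rows are softmax distributions; gate weights are None in baseline mode.
    """
    logits, alpha = model.logits(sentence, force_alpha=force_alpha)
    probs = ad.softmax(logits, axis=-1).data
    return probs, (alpha.data if alpha is not None else None)


def predict_tags(model: NERModel, sentences: Sequence[Sentence],
                 repair: bool = False) -> list[list[str]]:
    """Greedy per-token argmax decoding; ties go to the lowest label id.

    Tokens beyond the encoder window are predicted ``O``.  ``repair=True``
    applies the B-tag repair postprocessor per sentence.
    """
    out = []
    for sent in sentences:
        probs, _ = model_forward(model, sent)
        tags = [model.tag_vocab.tag(int(i)) for i in probs.argmax(axis=1)]
        tags += ["O"] * (sent.n - len(tags))
        if repair:
            tags = repair_bio(tags)
        out.append(tags)
    return out


# ---------------------------------------------------------------------------
# Training

@dataclass
class TrainResult:
    model: NERModel
    log: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_dev_f1: float = 0.0
    parse_head: "Linear | None" = None
    parse_vocab: LabelVocab | None = None


def _batch_iter(n: int, batch_size: int, order: np.ndarray):
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _validate_labels(train, dev, tag_vocab: TagVocab):
    for sent in dev:
        for t in sent.tokens:
            tag_vocab.id(t.tag)  # raises on unseen


def build_model(train: Sequence[Sentence], config: ModelConfig,
                rng: np.random.Generator) -> NERModel:
    """Construct an untrained model with vocabularies from a training corpus."""
    word_vocab = WordVocab.from_corpus(train)
    tag_vocab = TagVocab(t.tag for s in train for t in s.tokens)
    relations = head_vocab = rel_vocab = None
    if config.syntax_mode == "graph":
        relations = RelationVocab(sorted({t.deprel for s in train for t in s.tokens
                                          if t.deprel}))
    elif config.syntax_mode == "seqlab":
        head_vocab, rel_vocab = build_label_vocab(list(train), config.scheme, joint=False)
    return NERModel(config, word_vocab, tag_vocab, rng, relations=relations,
                    head_vocab=head_vocab, rel_vocab=rel_vocab)


def _train(train: Sequence[Sentence], dev: Sequence[Sentence], config: ModelConfig,
           mtl: bool) -> TrainResult:
    if not train:
        raise ValidationError("empty training corpus")
    for name, corpus in (("train", train), ("dev", dev)):
        for s in corpus:
            if any(t.tag is None for t in s.tokens):
                raise ValidationError(f"{name} corpus sentence lacks BIO tags")
    needs_parse = mtl or config.syntax_mode != "none"
    if needs_parse:
        for s in train:
            if any(t.head is None for t in s.tokens):
                raise ValidationError("training requires dependency trees in this mode")

    ss = np.random.SeedSequence(config.seed)
    init_s, shuffle_s, drop_s, parse_s = ss.spawn(4)
    init_rng = np.random.default_rng(init_s)
    shuffle_rng = np.random.default_rng(shuffle_s)
    drop_rng = np.random.default_rng(drop_s)

    cfg = replace(config, syntax_mode="none") if mtl else config
    model = build_model(train, cfg, init_rng)
    _validate_labels(train, dev, model.tag_vocab)

    parse_head = None
    parse_vocab = None
    parse_targets = None
    if mtl:
        parse_rng = np.random.default_rng(parse_s)
        if config.mtl_joint:
            parse_vocab = build_label_vocab(list(train), config.scheme, joint=True)
            parse_head = Linear(parse_rng, config.hidden, len(parse_vocab))
            parse_targets = [
                np.array([parse_vocab.id(l.joint())
                          for l in encode_dependencies(s, config.scheme)], dtype=np.intp)
                for s in train]
        else:
            # separate-task mode: one decoder per label component
            hv, rv = build_label_vocab(list(train), config.scheme, joint=False)
            parse_vocab = (hv, rv)
            parse_head = (Linear(parse_rng, config.hidden, len(hv)),
                          Linear(parse_rng, config.hidden, len(rv)))
            parse_targets = [
                (np.array([hv.id(l.head_code)
                           for l in encode_dependencies(s, config.scheme)], dtype=np.intp),
                 np.array([rv.id(l.deprel)
                           for l in encode_dependencies(s, config.scheme)], dtype=np.intp))
                for s in train]

    params = model.parameters()
    if parse_head is not None:
        heads = parse_head if isinstance(parse_head, tuple) else (parse_head,)
        for j, ph in enumerate(heads):
            for k, v in ph.parameters().items():
                params[f"parse_head.{j}.{k}"] = v
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)

    result = TrainResult(model=model, parse_head=parse_head, parse_vocab=parse_vocab)
    best_state = None
    bad_epochs = 0
    tag_ids = [model.tag_vocab.ids(s.tags) for s in train]

    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(train))
        total_ner = total_parse = 0.0
        n_batches = 0
        for batch in _batch_iter(len(train), config.batch_size, order):
            opt.zero_grad()
            terms = []
            n_tokens = 0
            parse_terms = []
            for idx in batch:
                sent = train[idx]
                n = min(sent.n, config.max_len)
                if mtl:
                    # one shared encoder pass feeds both task decoders
                    h = model.encoder(model.encoder.vocab.ids(sent.forms[:n]))
                    ner_in = h
                    if config.dropout > 0:
                        keep = (drop_rng.random(h.shape) >= config.dropout) / (1 - config.dropout)
                        ner_in = ad.mul(h, ad.constant(keep))
                    logits = model.classifier(ner_in)
                    if config.mtl_joint:
                        p_ce = ad.cross_entropy(parse_head(h), parse_targets[idx][:n])
                    else:
                        ht, rt = parse_targets[idx]
                        p_ce = ad.add(ad.cross_entropy(parse_head[0](h), ht[:n]),
                                      ad.cross_entropy(parse_head[1](h), rt[:n]))
                    parse_terms.append(ad.scale(p_ce, n))
                else:
                    logits, _ = model.logits(sent, train_mode=True, drop_rng=drop_rng)
                terms.append(ad.scale(ad.cross_entropy(logits, tag_ids[idx][:n]), n))
                n_tokens += n
            ner_loss = terms[0]
            for t in terms[1:]:
                ner_loss = ad.add(ner_loss, t)
            ner_loss = ad.scale(ner_loss, 1.0 / n_tokens)
            loss = ad.scale(ner_loss, config.w_ner) if mtl else ner_loss
            parse_loss_val = None
            if mtl:
                p_loss = parse_terms[0]
                for t in parse_terms[1:]:
                    p_loss = ad.add(p_loss, t)
                p_loss = ad.scale(p_loss, 1.0 / n_tokens)
                loss = ad.add(loss, ad.scale(p_loss, config.w_parse))
                parse_loss_val = float(p_loss.data)
                total_parse += parse_loss_val
            ad.backward(loss)
            opt.step()
            total_ner += float(ner_loss.data)
            n_batches += 1
        pred = predict_tags(model, dev)
        prf = evaluate_entities([s.tags for s in dev], pred)
        entry = {"epoch": epoch, "train_loss": total_ner / n_batches,
                 "dev_precision": prf.precision, "dev_recall": prf.recall,
                 "dev_f1": prf.f1}
        if mtl:
            entry["parse_loss"] = total_parse / n_batches
        result.log.append(entry)
        if prf.f1 > result.best_dev_f1 or best_state is None:
            result.best_dev_f1 = prf.f1
            result.best_epoch = epoch
            best_state = model.clone_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
        if bad_epochs > config.patience or result.best_dev_f1 >= 1.0:
            break
    model.load_state_dict(best_state)
    return result


def train_model(train: Sequence[Sentence], dev: Sequence[Sentence],
                config: ModelConfig) -> TrainResult:
    """Single-task training: masked token cross-entropy, AdamW, early stopping
    on dev strict entity F1 (which also selects the returned parameters)."""
    return _train(train, dev, config, mtl=False)


def train_multitask(train: Sequence[Sentence], dev: Sequence[Sentence],
                    config: ModelConfig) -> TrainResult:
    """Joint NER + sequence-labelling-parsing training with a shared encoder.

    Separate linear decoders per task; joint (head_code, deprel) parse labels;
    model selection by dev NER F1 only.  No fusion gate — syntax reaches NER
    only through the shared encoder.
    """
    return _train(train, dev, replace(config, mtl=True), mtl=True)


def parse_label_accuracy(result: TrainResult, corpus: Sequence[Sentence]) -> float:
    """Labeled accuracy of the MTL parse decoder over a corpus.

    In separate-task mode a token counts as correct only when both the head
    code and the relation are right.
    """
    if result.parse_head is None:
        raise ValidationError("not a multi-task model")
    model = result.model
    correct = total = 0
    for sent in corpus:
        n = min(sent.n, model.config.max_len)
        enc = model.encoder(model.encoder.vocab.ids(sent.forms[:n]))
        labs = encode_dependencies(sent, model.config.scheme)[:n]
        if isinstance(result.parse_head, tuple):
            hv, rv = result.parse_vocab
            hp = result.parse_head[0](enc).data.argmax(axis=1)
            rp = result.parse_head[1](enc).data.argmax(axis=1)
            gold_h = np.array([hv.id(l.head_code) for l in labs])
            gold_r = np.array([rv.id(l.deprel) for l in labs])
            correct += int(((hp == gold_h) & (rp == gold_r)).sum())
        else:
            pred = result.parse_head(enc).data.argmax(axis=1)
            gold = np.array([result.parse_vocab.id(l.joint()) for l in labs])
            correct += int((pred == gold).sum())
        total += n
    return correct / total


# ---------------------------------------------------------------------------
# Persistence (model directory: JSON config/vocabs + npz weights)

def save_model(result: TrainResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = result.model
    meta = {
        "config": asdict(model.config),
        "words": model.encoder.vocab.words,
        "tags": model.tag_vocab.tags,
        "log": result.log,
    }
    if model.relations is not None:
        meta["deprels"] = sorted({n[:-2] for n in
                                  (model.relations.name(i) for i in range(2, len(model.relations)))})
    if model.labemb is not None:
        meta["head_codes"] = model.labemb.head_vocab.labels
        meta["deprel_labels"] = model.labemb.rel_vocab.labels
    (outdir / "model.json").write_text(json.dumps(meta, indent=1))
    np.savez(outdir / "weights.npz", **model.state_dict())


def load_model(outdir: str | Path) -> NERModel:
    outdir = Path(outdir)
    meta = json.loads((outdir / "model.json").read_text())
    cfg = ModelConfig(**meta["config"])
    word_vocab = WordVocab(meta["words"])
    tag_vocab = TagVocab(meta["tags"])
    relations = RelationVocab(meta["deprels"]) if "deprels" in meta else None
    head_vocab = LabelVocab(meta["head_codes"]) if "head_codes" in meta else None
    rel_vocab = LabelVocab(meta["deprel_labels"]) if "deprel_labels" in meta else None
    rng = np.random.default_rng(0)
    model = NERModel(cfg, word_vocab, tag_vocab, rng, relations=relations,
                     head_vocab=head_vocab, rel_vocab=rel_vocab)
    with np.load(outdir / "weights.npz") as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model
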