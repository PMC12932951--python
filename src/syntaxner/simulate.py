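"""Seeded generator of joint NER + dependency corpora.

Sentences are sampled by recursively expanding a clause skeleton — a root
verb with argument noun phrases, optional prepositional phrases, and a final
punctuation mark; noun phrases expand into optional determiner / adjectival
/ nominal-compound modifiers before their head noun.  The resulting trees
are always valid (single root, acyclic) and projective.  Entity mentions
are contiguous subtrees headed by a noun, with their compound and amod
dependents inside the span — exactly the structures (compounds, modifiers,
function words) that dominate NER error analyses.

Two coupling modes control what determines an entity's TYPE:

* ``lexical`` — the type follows the lexeme (each type has its own lexeme
  pool).  Context alone suffices; syntax is redundant.
* ``syntax_determined`` — every entity lexeme comes from one type-ambiguous
  shared pool and the type is a deterministic function of the span head's
  dependency relation, which is drawn independently of the surface string.
  By construction the mutual information between lexeme (indeed, the whole
  surface sentence) and type is zero, so a purely lexical model cannot beat
  chance on the type decision while a syntax-aware model can be perfect.
  This makes "does syntax help?" a measurable property of the method rather
  than an artifact of any particular benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Sentence, Token
from .errors import ValidationError

DEFAULT_DEPRELS = ("nsubj", "obj", "pobj", "compound", "amod", "det", "prep", "punct", "root")

DEFAULT_VOCAB = {
    "verbs": ["reported", "developed", "received", "noted", "showed", "followed"],
    "nouns": ["patient", "doctor", "clinic", "dose", "visit", "chart", "nurse", "day"],
    "amods": ["severe", "acute", "mild", "chronic", "persistent", "left"],
    "compounds": ["skin", "heart", "muscle", "vaccine", "blood", "nerve"],
    "dets": ["the", "a"],
    "preps": ["in", "of", "after", "with"],
    "punct": ["."],
    # type-ambiguous shared pool (syntax_determined mode)
    "ambiguous_entities": ["rash", "fever", "edema", "nausea", "syncope",
                           "tremor", "pruritus", "myalgia"],
    # per-type pools (lexical mode)
    "typed_entities": {
        "Disorder": ["rash", "fever", "edema", "nausea"],
        "Drug": ["ibuprofen", "aspirin", "insulin", "heparin"],
    },
}


@dataclass
class GenConfig:
    n_sentences: int
    seed: int
    length_range: tuple[int, int] = (5, 12)
    entity_types: tuple[str, ...] = ("Disorder", "Drug")
    coupling: str = "syntax_determined"
    entity_rate: float = 0.7
    max_modifiers: int = 2
    vocab: dict = field(default_factory=lambda: dict(DEFAULT_VOCAB))
    deprels: tuple[str, ...] = DEFAULT_DEPRELS

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"bad length range {self.length_range}")
        if hi < 4:
            raise ValidationError("length range too small for clause skeleton "
                                  "(verb + argument + punct)")
        if self.coupling not in ("lexical", "syntax_determined"):
            raise ValidationError(f"unknown coupling mode {self.coupling!r}")
        if self.coupling == "syntax_determined" and len(self.entity_types) < 2:
            raise ValidationError("syntax_determined mode needs >= 2 entity types")
        if not (0.0 <= self.entity_rate <= 1.0):
            raise ValidationError("entity rate must be in [0, 1]")

    def deprel_type_map(self) -> dict[str, str]:
        """Deterministic span-head-deprel -> entity-type map (syntax mode).

        The first len(entity_types) argument relations, in a fixed order,
        each select one type.
        """
        arg_rels = ["nsubj", "obj", "pobj"][: len(self.entity_types)]
        if len(arg_rels) < len(self.entity_types):
            raise ValidationError("at most 3 entity types supported in syntax_determined mode")
        return dict(zip(arg_rels, self.entity_types))


@dataclass
class _NP:
    """A noun phrase under construction."""
    mods: list[tuple[str, str]]  # (form, deprel) before the head
    head_form: str
    entity_type: str | None      # None: not an entity
    slot_deprel: str             # attachment of the head to its governor


def _make_np(cfg: GenConfig, rng: np.random.Generator, slot_deprel: str,
             allow_entity: bool, budget: int) -> _NP:
    v = cfg.vocab
    is_entity = allow_entity and rng.random() < cfg.entity_rate
    mods: list[tuple[str, str]] = []
    n_mods = int(rng.integers(0, cfg.max_modifiers + 1))
    n_mods = min(n_mods, max(budget - 1, 0))
    if is_entity:
        if cfg.coupling == "syntax_determined":
            # The type-revealing relation sits on the span head, and the
            # fusion is token-local, so every span token must carry it:
            # spans in this mode are the bare head noun.
            type_map = cfg.deprel_type_map()
            rel = str(rng.choice(sorted(type_map)))
            etype = type_map[rel]
            head = str(rng.choice(v["ambiguous_entities"]))
            return _NP([], head, etype, rel)
        etype = str(rng.choice(cfg.entity_types))
        head = str(rng.choice(v["typed_entities"][etype]))
        for _ in range(n_mods):
            kind = rng.choice(["amod", "compound"])
            pool = v["amods"] if kind == "amod" else v["compounds"]
            mods.append((str(rng.choice(pool)), kind))
        return _NP(mods, head, etype, slot_deprel)
    head = str(rng.choice(v["nouns"]))
    if n_mods and rng.random() < 0.5:
        mods.append((str(rng.choice(v["dets"])), "det"))
        n_mods -= 1
    for _ in range(n_mods):
        kind = rng.choice(["amod", "compound"])
        pool = v["amods"] if kind == "amod" else v["compounds"]
        mods.append((str(rng.choice(pool)), kind))
    return _NP(mods, head, None, slot_deprel)


def generate_sentence(cfg: GenConfig, rng: np.random.Generator) -> Sentence:
    v = cfg.vocab
    lo, hi = cfg.length_range
    target = int(rng.integers(lo, hi + 1))

    # clause skeleton: subject NP, verb, object NP, optional PPs, punct
    budget = max(target - 3, 1)  # verb + punct + at least the object head
    has_subject = target >= 5 and rng.random() < 0.9
    subj = None
    if has_subject:
        subj_budget = max(1, budget // 2)
        subj = _make_np(cfg, rng, "nsubj", allow_entity=True, budget=subj_budget)
        budget -= 1 + len(subj.mods)
    obj = _make_np(cfg, rng, "obj", allow_entity=True, budget=max(budget, 1))
    budget -= 1 + len(obj.mods)
    pps: list[tuple[str, _NP]] = []
    while budget >= 2 and rng.random() < 0.5:
        prep = str(rng.choice(v["preps"]))
        np_budget = budget - 1
        pp_np = _make_np(cfg, rng, "pobj",
                         allow_entity=cfg.coupling == "lexical", budget=np_budget)
        pps.append((prep, pp_np))
        budget -= 2 + len(pp_np.mods)

    # lay out tokens left to right, recording head offsets afterwards
    forms: list[str] = []
    heads: list[int] = []
    deprels: list[str] = []
    tags: list[str] = []

    def emit_np(np_: _NP, governor_slot: list[int]):
        head_pos = len(forms) + len(np_.mods) + 1  # 1-based position of head
        first_span_tok = None
        for form, rel in np_.mods:
            forms.append(form)
            heads.append(head_pos)
            deprels.append(rel)
            if np_.entity_type is not None and rel in ("amod", "compound"):
                if first_span_tok is None:
                    first_span_tok = len(forms) - 1
                    tags.append(f"B-{np_.entity_type}")
                else:
                    tags.append(f"I-{np_.entity_type}")
            else:
                tags.append("O")
        forms.append(np_.head_form)
        heads.append(0)  # patched by caller
        governor_slot.append(len(forms))  # head's 1-based index
        deprels.append(np_.slot_deprel)
        if np_.entity_type is not None:
            tags.append(f"I-{np_.entity_type}" if first_span_tok is not None
                        else f"B-{np_.entity_type}")
        else:
            tags.append("O")

    subj_idx: list[int] = []
    obj_idx: list[int] = []
    if subj is not None:
        emit_np(subj, subj_idx)
    verb_pos = len(forms) + 1
    forms.append(str(rng.choice(v["verbs"])))
    heads.append(0)
    deprels.append("root")
    tags.append("O")
    emit_np(obj, obj_idx)
    pp_positions: list[tuple[int, list[int]]] = []
    for prep, pp_np in pps:
        prep_pos = len(forms) + 1
        forms.append(prep)
        heads.append(verb_pos)
        deprels.append("prep")
        tags.append("O")
        idx: list[int] = []
        emit_np(pp_np, idx)
        pp_positions.append((prep_pos, idx))
    forms.append(str(rng.choice(v["punct"])))
    heads.append(verb_pos)
    deprels.append("punct")
    tags.append("O")

    # patch argument heads
    if subj is not None:
        heads[subj_idx[0] - 1] = verb_pos
    heads[obj_idx[0] - 1] = verb_pos
    for prep_pos, idx in pp_positions:
        heads[idx[0] - 1] = prep_pos

    tokens = [Token(index=i, form=f, head=h, deprel=d, tag=t)
              for i, (f, h, d, t) in enumerate(zip(forms, heads, deprels, tags), start=1)]
    return Sentence(tokens)


def generate_corpus(config: GenConfig) -> list[Sentence]:
    """Generate ``config.n_sentences`` sentences; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    return [generate_sentence(config, rng) for _ in range(config.n_sentences)]


def generate_splits(config: GenConfig, n_train: int, n_dev: int, n_test: int
                    ) -> tuple[list[Sentence], list[Sentence], list[Sentence]]:
    """Three disjoint splits drawn from one stream (sizes override n_sentences)."""
    cfg = GenConfig(**{**vars(config), "n_sentences": n_train + n_dev + n_test})
    corpus = generate_corpus(cfg)
    return (corpus[:n_train], corpus[n_train:n_train + n_dev],
            corpus[n_train + n_dev:])
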