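# syntaxner

Syntax-infused named entity recognition for biomedical-style text: a
token-level tagger that fuses **contextual** token representations with
**explicit dependency-syntax** representations through a learned attention
gate, together with a multi-task variant, strict entity-level evaluation,
dependency-aware error analysis, and a seeded synthetic corpus generator so
that every experiment runs self-contained on one CPU.

It is written for NLP practitioners who want to measure — not assume — what
explicit syntax contributes to span detection and typing: biomedical NER is
exactly the setting where entity boundaries track noun-phrase structure
(compounds, adjectival modifiers, function words) and where boundary errors
on a single token lose the whole entity under strict scoring.

## The model

Each token i gets two vectors in R^H:

* **h_i** — a contextual embedding from an encoder over the word sequence.
  Any callable mapping words to an n×H matrix satisfies the adapter
  contract; the shipped encoder is a compact trainable self-attention
  network (pretrained transformer backbones plug in via first-subword
  alignment, `align_subwords`).
* **g_i** — a syntactic embedding from one of two alternative pathways:
  1. **graph** — the parse becomes a typed directed graph (forward edge
     r→, inverse edge r←, SELF loops) encoded by a multi-headed
     relational graph attention network (RGAT);
  2. **seqlab** — the tree is linearized to one label per token,
     (head position, dependency relation), with relative (signed offset)
     or absolute (sentence position) head encoding, and the label is
     embedded component-wise.

A lightweight feedforward attention network gates the two per token:

```
z_i = [h_i ; g_i]                        ∈ R^{2H}
a_i = Softmax(W2 · tanh(W1 z_i + b1) + b2) ∈ R^2,  a_i = [α_h, α_g]
f_i = α_h · h_i + α_g · g_i
```

so α_h + α_g = 1 and f_i is a convex per-token mixture — context where it
is informative, syntax where structure marks the boundary better.  The
fused vector passes through dropout into a linear softmax classifier over
BIO tags.  `syntax_mode="none"` is the pure fine-tuning baseline: no
syntax computation is reachable.  The multi-task variant drops the gate
and instead trains NER jointly with parsing-as-sequence-labelling through
a shared encoder and separate linear decoders
(loss = w_ner·L_ner + w_parse·L_parse).

Scoring is strict entity-level micro P/R/F1 (an entity counts only when
span boundaries *and* type match exactly), with a token-level variant, a
B-tag repair postprocessor for the orphan-I failure mode
(`[O, I-X, I-X] → [O, B-X, I-X]`), and error analyses by mistagged token
form, by gold dependency relation, and by distance to the syntactic head.

## Worked example

`python examples/train_and_compare.py` generates a corpus in
*syntax-determined* mode — entity lexemes are shared across types and the
type is a function of the span head's dependency relation, so surface text
alone cannot decide it — and trains the baseline and both syntax pathways
with the same budget:

```
600 train / 100 dev / 200 test sentences

syntax_mode=none    test P=0.460 R=0.460 F1=0.460  (6 epochs, 2s)
syntax_mode=seqlab  test P=1.000 R=1.000 F1=1.000  (2 epochs, 1s)
syntax_mode=graph   test P=1.000 R=0.996 F1=0.998  (1 epochs, 2s)
```

The baseline finds the spans (they are lexically marked) but types them at
chance (~0.5); either syntax pathway reads the type off the parse.  The
other scripts in `examples/` walk through corpus generation, tree
linearization, the gate algebra, multi-task training, and error analysis.

A CLI mirrors the library for shell use:

```
syntaxner simulate  --config gen.yaml --out data/
syntaxner linearize --scheme rel --in data/train.conllu --out train.labels.tsv
syntaxner train     --config train.yaml
syntaxner predict   --model model/ --in data/test.tsv --out pred.bio --repair
syntaxner evaluate  --gold data/test.bio --pred pred.bio
syntaxner analyze   --gold data/test.tsv --pred pred.bio --out report/
```

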