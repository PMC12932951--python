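# Methods

## Task and representations

The package tags tokenized sentences with BIO entity labels.  Entity spans
are 0-based half-open `(start, end, type)` triples internally; the strict
IOB2 reading is used throughout: a span opens only with `B-X`, and an
`I-X` that does not continue a same-type run is an orphan contributing no
entity.  This matches the scoring convention under which a single missing
B-tag loses the whole entity, which is also why the B-tag repair
postprocessor exists (below).

Dependency analyses follow Universal-Dependencies-style conventions: each
token has one head (0 = virtual root) and a relation label.  Trees are
validated on demand, not on construction, because parser output may be
imperfect and the pipeline must carry it anyway.

## Contextual pathway

The encoder contract is minimal — words in, an n×H matrix out — so any
backbone can stand behind it.  The shipped implementation is a trainable
self-attention encoder: learned word and position embeddings, one
multi-head attention block with a feedforward sublayer (tanh
nonlinearities), H = 32 by default.  It is deliberately small: every
experiment in this repository trains from scratch on one CPU in seconds to
minutes.  For subword backbones, `align_subwords` implements first-piece
pooling (the dominant convention for token classification; it keeps the
alignment exact and deterministic), and the loss is only ever computed on
word-level positions.

## Graph pathway (RGAT)

A parsed sentence becomes a typed directed multigraph: for every arc
head→dependent with relation r, a forward edge typed r→ and an inverse
edge typed r←, plus one SELF loop per node.  Inverse edges and self-loops
are not optional decoration: without them, leaves would receive no
messages and information could not flow dependent→head.  A valid tree
therefore has exactly 2(n−1)+n edges.

The encoder is a stack (default L = 2) of relational graph attention
layers with K = 4 heads.  Per layer and head, each node attends over its
incoming edges: the source state is transformed by a relation-specific
matrix, scored against a (shared) transform of the target state through an
additive function with a leaky-rectifier nonlinearity, and normalized by
softmax over *all* of the node's incoming edges jointly (across relations).
Attention-weighted sums are concatenated over heads, projected, and passed
through tanh; a final linear projection yields the n×H structured
embeddings.  Relational graph attention admits several variants
(within-relation vs across-relation normalization); the across-relation
form used here is the simplest one consistent with per-node normalization,
and L, K, residual connections and dropout are config-exposed rather than
claimed as canonical.  Relations unseen in training map to a reserved UNK
edge type with a warning — inference never fails on a new parser label.

With L layers a node's output depends only on features within L hops
(tested); outputs are permutation-equivariant in the node labelling
(tested); evaluation-mode outputs are bitwise reproducible because the
whole stack is plain float64 numpy.

## Sequence-labelling pathway

A tree is linearized to one label per token: a head code plus the
relation.  Relative encoding uses the signed offset head − index with a
dedicated root symbol "R" (position-independent and compact; an offset
−index would make the label space grow with position).  Absolute encoding
uses the head's printed 1-based position, "0" for root.  Decoding is
total: unparsable or out-of-range codes (including self-reference) attach
to the virtual root and are flagged — root attachment can never create a
cycle, which is the standard fallback for sequence-labelling parsers.
Round-tripping any valid tree is exact with zero repairs (property-tested
over random trees, projective or not).

The embedder maps head codes and relations through separate tables
(default 64 and 32 dimensions — the two vocabularies differ hugely in
size, which is why concatenate-then-project is used rather than a sum)
and projects to H with tanh.  It is position-independent by construction:
positional information lives entirely in the head code.  Whether to embed
the joint (head, relation) label or its components separately is not
dictated by anything deeper than vocabulary economics; component-wise is
the default here.

## Fusion gate

For each token, z_i = [h_i; g_i], a_i = Softmax(W2·tanh(W1 z_i + b1) + b2)
with W1 ∈ R^{H×2H}, W2 ∈ R^{2×H}, and f_i = α_h h_i + α_g g_i.  The gate
parameters are shared across tokens and sentences — the equations involve
only the token's own z_i, and per-token parameters would be unlearnable.
Consequences asserted in tests: α_h + α_g = 1; f_i is a componentwise
convex combination; W2 = 0 gives the plain average; saturating b2 pins the
output to one pathway, and forcing α = (1, 0) reproduces the baseline
model's probabilities exactly given shared encoder/classifier parameters.
Dropout (default rate 0.1) is applied after fusion, before the classifier.
The two syntax pathways are strict alternatives selected by configuration;
there is no hybrid mode.

## Classifier, training, prediction

A linear softmax layer maps f_i (or h_i in baseline mode) to tag
probabilities.  Decoding is per-token argmax with ties broken toward the
lowest tag id (tags are ordered lexicographically); there is deliberately
no CRF — the design under study is a standard classification layer, and
structure enters through the representations, not the decoder.  Optional
postprocessing rewrites the first token of every orphan I-run to B
(idempotent; it only adds spans, so strict recall can only go up — note
token-level accuracy can go *down* when an orphan I happened to match a
gold I, which is why only the span-level monotonicity is asserted).

Training minimizes mean token-level cross-entropy (padding positions
masked out; padded and unpadded batching give identical losses because
attention is masked too) with AdamW, learning rate 3e-3, weight decay
0.01, batch size 16, at most 20 epochs by default with early stopping
(patience 3) on dev strict entity F1, which also selects the returned
parameters.  A single learning rate is used because the shipped encoder
is trained from scratch; a fine-tuned pretrained backbone would warrant a
split rate.  All randomness (init, shuffling, dropout) derives from one
seed through independent spawned streams, so runs are exactly
reproducible.  Sentences longer than the encoder window (default 64) are
truncated with a warning and their overflow tokens predicted O.

## Multi-task variant

NER and parsing-as-sequence-labelling share the encoder; each task has its
own linear decoder (joint head+relation labels by default; separate
component decoders behind a flag).  Total loss is
w_ner·L_ner + w_parse·L_parse (defaults 1, 1); model selection uses dev
NER F1 only; the fusion gate is absent — syntax reaches NER only through
the shared representation.  The parse head's parameters come from their
own seeded stream, so setting w_parse = 0 reproduces the single-task
trajectory bit-for-bit (asserted), which pins down that the auxiliary task
— not an architectural side effect — causes any difference.  Parse targets
are the trees attached to the training corpus; whether those came from a
parser or gold annotation is the caller's choice.

## Evaluation and error analysis

Strict entity-level micro P/R/F1 intersects gold and predicted span sets
as exact (start, end, type) triples; it is cross-checked in tests against
an independent brute-force extractor on 10,000 random pairs, and corpus
counts are additive (micro-consistency).  The token-level variant counts
each non-O token individually.

`analyze_errors` reports: (a) mistagged-token form frequencies; (b) mistag
counts by gold dependency relation; (c) a normalized error-rate curve —
for each distance d, mistagged tokens at d over all tokens at d, where
distance is |index − head| and root-attached tokens are binned separately
at 0; (d) entity-error categories: *type_mismatch* (exact boundaries,
wrong type), *span_mismatch* (overlap of at least one token, boundaries
wrong — whether or not the type also differs), *false_negative* (gold span
overlapping no prediction), *false_positive* (prediction overlapping no
gold span).  The distance curve requires trees on the gold corpus; without
them it is omitted with a warning and the rest is still produced.

## Synthetic corpus generator

Sentences are sampled by recursively expanding a clause skeleton (root
verb, argument noun phrases, optional prepositional phrases, final
punctuation; noun phrases expand to determiner/amod/compound modifiers
before a head noun), giving valid, projective trees by construction and
surface structures — compounds, modifiers, function words — of the kind
that dominate real NER error tables.  Default conditions: sentence lengths
drawn from 5–12 tokens, two entity types, entity rate 0.7 per argument
slot, UD-like relation inventory (nsubj, obj, pobj, compound, amod, det,
prep, punct, root).

The *lexical* coupling mode ties entity type to the lexeme (per-type
pools) — context suffices, syntax is redundant.  The *syntax_determined*
mode draws every entity lexeme from one shared pool and sets the type by
the span head's relation (nsubj/obj, chosen by a fair coin independent of
everything on the surface), so the mutual information between surface and
type is zero by construction and a context-only model cannot beat chance
on typing, while a parse-reading model can be exact.  In this mode entity
spans are the bare head noun: the type-revealing relation sits on the span
head, the fusion is token-local, and a span-initial modifier's own label
(amod/compound) carries no argument relation — multi-token ambiguous
spans would make the type undecidable at exactly the token whose B-tag
the strict metric cares about most.  (The graph pathway could still
recover it through two-hop propagation; the label pathway could not, and
the generator is the controlled test bed for both.)  Modifier-bearing
entity spans remain in lexical mode, and modifier structure appears on
non-entity phrases in both modes.

What passing these tests shows: the architecture can extract and exploit
a syntactic signal that is genuinely absent from the surface, at the
stated problem sizes, and every algebraic contract holds.  What it does
not show: performance on real biomedical corpora — the generator imitates
structural, not lexical, statistics; real entities are rarer, longer,
noisier, and their annotation is inconsistent in ways no generator
reproduces.

## Problem sizes and numerics

The default experiment scripts use 2,000/200/500 train/dev/test sentences
for the separation experiment (three seeds per mode, four epochs, patience
two), 32 sentences for the overfit check (cap 200 epochs), 1,000 random
trees per scheme for round-trip checks, and 10,000 random pairs for the
scorer/oracle comparison — sizes chosen so the whole battery runs in
about a minute on a single CPU while keeping every stochastic margin wide
(the separation gap is ~0.5 F1 against a 0.25 tolerance band).

Everything numerical is float64 numpy with single-threaded deterministic
kernels; weights use Glorot-uniform init (embeddings: small normal);
softmaxes subtract the rowwise max; the per-segment softmax in the RGAT
subtracts per-segment maxima.  Degenerate inputs are contracts, not
crashes: empty label sequences, zero-piece words, overlapping spans and
length mismatches raise typed validation errors; unknown relations or
labels map to UNK rows; fully-masked loss raises rather than returning
NaN.

## Known limitations

* The shipped encoder is not pretrained; absolute scores on real corpora
  would hinge on a transformer backbone behind the adapter contract.
* The gate mixes exactly two pathways; no per-dimension gates, no
  three-way fusion.
* Graphs are word-level; subword graphs are out of scope.
* The generator's lexicon is tiny and its syntax templated; it is a
  controlled instrument, not a benchmark imitation.
* CoNLL-U multiword-token and empty-node lines are skipped on read (and
  therefore absent on write); all other columns round-trip byte-exactly.
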