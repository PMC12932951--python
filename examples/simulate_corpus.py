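"""Generate a small synthetic NER+dependency corpus and inspect it.

In syntax_determined mode the entity type is a function of the span head's
dependency relation (nsubj -> Disorder, obj -> Drug here), while the entity
words themselves come from one shared pool — so the printed sentences show
the same lexeme carrying different types depending on its grammatical role.
"""

from collections import Counter

from syntaxner import GenConfig, bio_to_spans, generate_corpus

cfg = GenConfig(n_sentences=200, seed=42, coupling="syntax_determined")
corpus = generate_corpus(cfg)

print(f"{len(corpus)} sentences; deprel->type map: {cfg.deprel_type_map()}\n")
for sent in corpus[:4]:
    print(" ".join(sent.forms))
    for tok in sent.tokens:
        print(f"  {tok.index:2d} {tok.form:12s} head={tok.head:2d} "
              f"{tok.deprel:8s} {tok.tag}")
    print()

by_lexeme = Counter()
for sent in corpus:
    for span in bio_to_spans(sent.tags):
        by_lexeme[(sent.tokens[span.end - 1].form, span.type)] += 1
print("entity (lexeme, type) counts — every lexeme occurs with both types:")
for (lex, typ), c in sorted(by_lexeme.items()):
    print(f"  {lex:10s} {typ:10s} {c}")
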