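"""Dependency trees as per-token labels: encode, decode, repair.

Shows both head encodings on one sentence, the exact round trip, and how
the total decoder repairs an impossible label to a root attachment instead
of failing.
"""

from syntaxner import (GenConfig, SyntaxLabel, decode_labels, encode_dependencies,
                       generate_corpus)

(sent,) = generate_corpus(GenConfig(n_sentences=1, seed=3))
print(" ".join(sent.forms))

for scheme in ("relative", "absolute"):
    labels = encode_dependencies(sent, scheme)
    print(f"\n{scheme} encoding:")
    for tok, lab in zip(sent.tokens, labels):
        print(f"  {tok.form:12s} -> {lab.head_code}@{lab.deprel}")
    heads, deprels, flags = decode_labels(labels, sent.n, scheme)
    assert heads == sent.heads and not any(flags)
    print(f"  round trip exact, {sum(flags)} repairs")

bad = [SyntaxLabel("+99", "obj"), SyntaxLabel("R", "root")]
heads, _, flags = decode_labels(bad, 2, "relative")
print(f"\nout-of-range label '+99' decoded to head {heads[0]} "
      f"(virtual root), flagged={flags[0]}")
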