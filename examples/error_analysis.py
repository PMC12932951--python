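"""Dependency-aware error analysis of an undertrained tagger.

Trains the baseline briefly so it still makes mistakes, then slices the
mismatches the way NER error studies do: by token form, by gold dependency
relation, by distance to the syntactic head, and by entity-error category.
"""

from syntaxner import (GenConfig, ModelConfig, analyze_errors, generate_splits,
                       predict_tags, train_model)

train, dev, test = generate_splits(GenConfig(n_sentences=1, seed=5), 200, 40, 100)
cfg = ModelConfig(syntax_mode="none", hidden=16, enc_heads=2,
                  max_epochs=1, seed=2)
result = train_model(train, dev, cfg)
pred = predict_tags(result.model, test)

report = analyze_errors(test, pred)
frames = report.to_frames()

print("most mistagged tokens:")
print(frames["tokens"].head(5).to_string(index=False))
print("\nmistags by gold dependency relation:")
print(frames["deprels"].head(5).to_string(index=False))
print("\nerror rate by distance to syntactic head (0 = root-attached):")
print(frames["distance"].to_string(index=False))
print("\nentity error categories:")
print(frames["categories"].to_string(index=False))
print("\nA span_mismatch overlaps gold with wrong boundaries; a type_mismatch "
      "has exact boundaries but the wrong type.")
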