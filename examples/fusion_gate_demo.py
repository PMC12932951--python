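"""The syntax-aware attention gate, numerically.

For each token: z = [h; g], a = Softmax(W2 tanh(W1 z + b1) + b2),
f = alpha_h h + alpha_g g.  The demo verifies the normalization
alpha_h + alpha_g = 1 and the closed forms the equations imply.
"""

import numpy as np

from syntaxner import FusionGate, fuse_representations

rng = np.random.default_rng(0)
H = 4
gate = FusionGate(rng, H)
h = rng.normal(size=(3, H))
g = rng.normal(size=(3, H))

outs = fuse_representations(h, g, gate)
for i, o in enumerate(outs):
    print(f"token {i}: alpha_h={o.alpha_h:.4f} alpha_g={o.alpha_g:.4f} "
          f"sum={o.alpha_h + o.alpha_g:.10f}")

gate.W2.data[:] = 0.0
gate.b2.data[:] = 0.0
(o, *_) = fuse_representations(h, g, gate)
print("\nW2=0, b2=0 -> equal logits -> plain average; max |f - (h+g)/2| =",
      np.abs(o.f - (h[0] + g[0]) / 2).max())

gate.b2.data[:] = (50.0, -50.0)
(o, *_) = fuse_representations(h, g, gate)
print("b2=(+50,-50)  -> gate saturates to context;  max |f - h| =",
      np.abs(o.f - h[0]).max())
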