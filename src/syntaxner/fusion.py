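"""The syntax-aware attention gate.

For each token i the contextual vector h_i and the syntactic vector g_i
(both in R^H) are merged by a lightweight feedforward attention network:

    z_i = [h_i ; g_i]                                  in R^{2H}
    a_i = Softmax(W2 . tanh(W1 z_i + b1) + b2)         in R^2
    f_i = alpha_h . h_i + alpha_g . g_i

with W1 in R^{H x 2H} and W2 in R^{2 x H}.  The two attention weights
a_i = [alpha_h, alpha_g] are softmax-normalized, so alpha_h + alpha_g = 1
and f_i is a convex combination of the two pathways: the model leans on
context where it is informative and falls back on syntax where structure
marks the entity boundary better.  The gate parameters are shared across
tokens and sentences — the equations involve only the token's own z_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .nn import Module, glorot
from .nn import autodiff as ad


def _transpose(w: ad.Tensor) -> ad.Tensor:
    def bwd(g):
        if w.requires_grad:
            w._accum(g.T)

    return ad.Tensor(w.data.T, parents=(w,), backward_fn=bwd)


def _column(a: ad.Tensor, j: int) -> ad.Tensor:
    """Column j of a 2-D tensor as (n, 1), with gradient flow."""

    def bwd(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            acc[:, j] = g[:, 0]
            a._accum(acc)

    return ad.Tensor(a.data[:, j:j + 1], parents=(a,), backward_fn=bwd)


class FusionGate(Module):
    """Learned two-way gate; holds W1 (H x 2H), b1 (H), W2 (2 x H), b2 (2)."""

    def __init__(self, rng: np.random.Generator, hidden: int):
        self.W1 = ad.parameter(glorot(rng, 2 * hidden, hidden, shape=(hidden, 2 * hidden)))
        self.b1 = ad.parameter(np.zeros(hidden))
        self.W2 = ad.parameter(glorot(rng, hidden, 2, shape=(2, hidden)))
        self.b2 = ad.parameter(np.zeros(2))

    def forward(self, h: ad.Tensor, g: ad.Tensor,
                force_alpha: tuple[float, float] | None = None
                ) -> tuple[ad.Tensor, ad.Tensor]:
        """Fuse two (n, H) pathway tensors; returns (f (n, H), alpha (n, 2)).

        ``force_alpha`` pins the gate to fixed weights — (1, 0) makes the
        fused output equal the contextual pathway exactly.
        """
        if h.shape != g.shape:
            raise ValidationError(f"pathway shape mismatch: {h.shape} vs {g.shape}")
        z = ad.concat([h, g], axis=-1)                                  # (n, 2H)
        hid = ad.tanh(ad.add(ad.matmul(z, _transpose(self.W1)), self.b1))
        logits = ad.add(ad.matmul(hid, _transpose(self.W2)), self.b2)   # (n, 2)
        alpha = ad.softmax(logits, axis=-1)
        if force_alpha is not None:
            alpha = ad.constant(np.tile(np.asarray(force_alpha, dtype=np.float64),
                                        (h.shape[0], 1)))
        fused = ad.add(ad.mul(_column(alpha, 0), h), ad.mul(_column(alpha, 1), g))
        return fused, alpha


@dataclass(frozen=True)
class FusionOutput:
    """Fused vector f_i and its two gate weights for one token."""

    f: np.ndarray
    alpha_h: float
    alpha_g: float


def fuse_representations(h: np.ndarray, g: np.ndarray, gate: FusionGate) -> list[FusionOutput]:
    """Fuse two n x H pathway matrices token-wise (no gradients).

    Each token's gate is computed independently from its own concatenated
    feature vector z_i.
    """
    h = np.asarray(h, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if h.shape != g.shape:
        raise ValidationError(f"pathway shape mismatch: {h.shape} vs {g.shape}")
    fused, alpha = gate.forward(ad.constant(h), ad.constant(g))
    return [FusionOutput(f=fused.data[i].copy(),
                         alpha_h=float(alpha.data[i, 0]),
                         alpha_g=float(alpha.data[i, 1]))
            for i in range(h.shape[0])]
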