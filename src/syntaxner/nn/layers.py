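"""Parameter containers and small layers built on the autodiff core."""

from __future__ import annotations

import copy

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base: recursively exposes parameters as a flat name -> Tensor dict."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for k, v in state.items():
            params[k].data = np.array(v, dtype=np.float64, copy=True)

    def clone_state(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = glorot(rng, d_in, d_out)
        self.W = ad.parameter(w)
        self.b = ad.parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.W), self.b)


class Embedding(Module):
    """Lookup table with reserved rows handled by the caller's vocabulary."""

    def __init__(self, rng: np.random.Generator, n_rows: int, dim: int, scale: float = 0.1):
        self.table = ad.parameter(rng.normal(0.0, scale, size=(n_rows, dim)))

    def __call__(self, ids) -> Tensor:
        return ad.gather_rows(self.table, ids)


class AdamW:
    """Decoupled weight decay Adam over a dict of named Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            if self.wd:
                p.data -= self.lr * self.wd * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
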