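"""Neural-network modules built on the autograd core.

Modules hold their parameters as named ``Tensor`` attributes and expose a
flat ``state_dict`` (copies of the raw arrays) so checkpoint averaging can
operate on plain ndarrays.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .autograd import Tensor, conv2d, layer_norm, softmax


class Module:
    """Base class: parameter discovery and state (de)serialization."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out: Dict[str, Tensor] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict key mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}"
                )
            p.data = state[k].astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Conv2d(Module):
    """Channels-last 2-D convolution layer."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0):
        fan_in = k * k * c_in
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, c_in, c_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention with h heads."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, hd = self.n_heads, self.dim // self.n_heads

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, hd).transpose(0, 2, 1, 3)  # (B,h,T,hd)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * Tensor(np.asarray(1.0 / np.sqrt(hd)))
        att = softmax(scores)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.wo(ctx)


class TransformerUnit(Module):
    """Post-norm transformer encoder unit: self-attention + feed-forward."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm2 = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ff2(self.ff1(x).relu()))


class TransformerStack(Module):
    def __init__(self, n_units: int, dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator):
        self.units = [TransformerUnit(dim, n_heads, ff_dim, rng)
                      for _ in range(n_units)]

    def __call__(self, x: Tensor) -> Tensor:
        for unit in self.units:
            x = unit(x)
        return x
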