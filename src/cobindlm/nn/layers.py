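"""Neural-network layers used by the encoder, task heads, and contact CNN."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, embedding_lookup

DTYPE = np.float32


class Module:
    """Parameter container with named sub-modules, torch-free."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def set_trainable(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("array shape mismatch while loading state")
            p.data = np.array(a, dtype=p.data.dtype)


def _init(rng, *shape, scale=None):
    if scale is None:
        scale = 1.0 / np.sqrt(shape[-1] if len(shape) > 1 else shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape).astype(DTYPE), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = _init(rng, d_in, d_out, scale=1.0 / np.sqrt(d_in))
        self.bias = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = _init(rng, n, d, scale=0.02)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.shift = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gain + self.shift


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the cistrome axis.

    ``scaling="per_head"`` uses the standard 1/sqrt(d_head) factor;
    ``scaling="model_dim"`` divides scores by d_model instead.
    """

    def __init__(self, d_model: int, n_heads: int, rng, scaling: str = "per_head"):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if scaling not in ("per_head", "model_dim"):
            raise ValueError(f"unknown attention scaling {scaling!r}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.scale = (1.0 / np.sqrt(self.d_head)) if scaling == "per_head" else (1.0 / d_model)
        self.w_q = Linear(d_model, d_model, rng)
        self.w_k = Linear(d_model, d_model, rng)
        self.w_v = Linear(d_model, d_model, rng)
        self.w_o = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        *lead, P, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            t = t.reshape(*lead, P, h, dh)
            axes = list(range(t.ndim))
            axes[-3], axes[-2] = axes[-2], axes[-3]  # (..., h, P, dh)
            return t.transpose(*axes)

        q, k, v = split(self.w_q(x)), split(self.w_k(x)), split(self.w_v(x))
        kt_axes = list(range(q.ndim))
        kt_axes[-1], kt_axes[-2] = kt_axes[-2], kt_axes[-1]
        scores = (q @ k.transpose(*kt_axes)) * self.scale
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (..., h, P, dh)
        axes = list(range(ctx.ndim))
        axes[-3], axes[-2] = axes[-2], axes[-3]
        ctx = ctx.transpose(*axes).reshape(*lead, P, d)
        return self.w_o(ctx)


class TransformerBlock(Module):
    """Post-norm block: LN(x + attention(x)) then LN(x + feed-forward(x))."""

    def __init__(self, d_model: int, n_heads: int, ff_mult: int, rng, scaling="per_head"):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng, scaling)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_mult * d_model, rng)
        self.ff2 = Linear(ff_mult * d_model, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.attn(x))
        return self.ln2(x + self.ff2(self.ff1(x).relu()))


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        scale = 1.0 / np.sqrt(c_in * kernel * kernel)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.pad = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm", "MultiHeadSelfAttention",
    "TransformerBlock", "Conv2d", "Tensor", "concat", "DTYPE",
]
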