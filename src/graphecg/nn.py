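"""Neural-network building blocks on top of :mod:`graphecg.autodiff`.

Layers follow the usual module pattern: each owns named :class:`Tensor`
parameters, exposes ``__call__`` and recursively yields its parameters for the
optimizer.  Initialization is fan-based scaled uniform with an explicit
``numpy.random.Generator`` so every draw is reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, layer_norm, mean, softmax

__all__ = [
    "Module", "Linear", "Dropout", "LayerNorm", "MultiHeadSelfAttention",
    "FeedForward", "TransformerEncoderBlock", "Adam", "positional_encoding",
]


class Module:
    """Base class: parameter discovery via attribute walk."""

    def parameters(self) -> Iterator[Tensor]:
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _uniform_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Tensor(_uniform_init(rng, d_in, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; active only when a generator is passed (train mode)."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if rng is None or self.p == 0.0:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


def positional_encoding(T: int, d_model: int) -> np.ndarray:
    """Sinusoidal position code: PE[t, 2i] = sin(t/10000^(2i/d)), odd cols cos.

    Returns a constant ``(T, d_model)`` array; ``d_model`` must be even.
    """
    if T < 1:
        raise ValueError("sequence length must be >= 1")
    if d_model % 2 != 0:
        raise ValueError("d_model must be even for sin/cos pairing")
    pos = np.arange(T)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.zeros((T, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``h`` parallel heads.

    ``uniform_attention=True`` replaces the softmax weights with a uniform
    average over positions (the "no attention" ablation); the projections and
    output mixing are kept so parameter counts stay comparable.
    """

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator,
                 uniform_attention: bool = False):
        if d_model % heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by heads={heads}")
        self.d_model = d_model
        self.heads = heads
        self.d_k = d_model // heads
        self.uniform_attention = uniform_attention
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.heads, self.d_k).swapaxes(1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        q = self._split(self.wq(x), B, T)
        k = self._split(self.wk(x), B, T)
        v = self._split(self.wv(x), B, T)
        if self.uniform_attention:
            ctx = mean(v, axis=2, keepdims=True) + (v * 0.0)  # broadcast uniform mix
        else:
            scores = (q @ k.swapaxes(-1, -2)) / np.sqrt(self.d_k)
            weights = softmax(scores, axis=-1)
            ctx = weights @ v
        ctx = ctx.swapaxes(1, 2).reshape(B, T, self.d_model)
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, d_hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerEncoderBlock(Module):
    """Post-norm encoder block: attention + add&norm, FFN + add&norm."""

    def __init__(self, d_model: int, heads: int, dropout: float,
                 rng: np.random.Generator, uniform_attention: bool = False,
                 ff_mult: int = 4):
        self.attn = MultiHeadSelfAttention(d_model, heads, rng,
                                           uniform_attention=uniform_attention)
        self.norm1 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, ff_mult * d_model, rng)
        self.norm2 = LayerNorm(d_model)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x), rng))
        x = self.norm2(x + self.drop(self.ff(x), rng))
        return x


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
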