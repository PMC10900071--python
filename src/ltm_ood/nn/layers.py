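"""Neural-network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv3d, embedding, upsample_nearest3d

__all__ = [
    "Module", "Linear", "Embedding", "Conv3d", "UpConv3d", "LayerNorm",
    "InstanceNorm3d", "Dropout", "ResidualBlock3d", "CausalSelfAttention",
    "TransformerBlock",
]


class Module:
    """Base class; collects parameters by introspecting attributes."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        out, seen = [], set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in obj.__dict__.values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.w = Tensor(_kaiming(rng, (d_in, d_out), d_in), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Embedding(Module):
    def __init__(self, n_vocab: int, d: int, rng: np.random.Generator, scale: float = 0.02):
        self.w = Tensor((rng.standard_normal((n_vocab, d)) * scale).astype(np.float32),
                        requires_grad=True)

    def forward(self, idx: np.ndarray) -> Tensor:
        return embedding(self.w, idx)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        fan_in = c_in * kernel ** 3
        self.w = Tensor(_kaiming(rng, (c_out, c_in, kernel, kernel, kernel), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class UpConv3d(Module):
    """Nearest-neighbour 2x upsample followed by a stride-1 convolution.

    kernel=1 gives a cheap pure channel-mix; use a wider kernel where spatial
    smoothing after the upsample matters.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv3d(c_in, c_out, kernel, rng, stride=1, padding=kernel // 2)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(upsample_nearest3d(x, 2))


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.g + self.b


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes (no affine)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        return xc * ((var + self.eps) ** -0.5)


class Dropout(Module):
    """Inverted dropout; ``force_active`` keeps it stochastic at inference (MC dropout)."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p, self.rng = p, rng
        self.force_active = False

    def forward(self, x: Tensor) -> Tensor:
        if self.p == 0.0 or not (self.training or self.force_active):
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask.astype(np.float32)


class ResidualBlock3d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.c1 = Conv3d(channels, channels, kernel, rng, padding=kernel // 2)
        self.c2 = Conv3d(channels, channels, kernel, rng, padding=kernel // 2)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        return (x + self.c2(h)).relu()


class CausalSelfAttention(Module):
    """Exact multi-head causal self-attention (quadratic; fine at desk-scale n)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.proj = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(B, T, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]             # each (B, h, T, dh)
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        mask = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)
        att = (att + mask).softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(out)


class TransformerBlock(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 4):
        self.ln1 = LayerNorm(d_model)
        self.attn = CausalSelfAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.fc1 = Linear(d_model, mlp_ratio * d_model, rng)
        self.fc2 = Linear(mlp_ratio * d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    return concat([a, b], axis=1)
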