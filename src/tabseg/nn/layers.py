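"""Neural-network modules on the autodiff engine.

Conventions follow common frameworks: modules own named parameters, expose
``state_dict``/``load_state_dict`` for checkpointing, and a ``training`` flag
toggles dropout. Weight initialization is He-normal from an explicit
``numpy.random.Generator`` so construction is fully seeded.
"""
from __future__ import annotations

import math
from typing import Iterator, Optional

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, child in self._children.items():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules):
        super().__init__()
        self._items = list(modules)
        for i, m in enumerate(self._items):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.items = ModuleList(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, pad=None, bias=True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = (kernel // 2) if pad is None else pad
        self.weight = Parameter(_he_normal(rng, (cout, cin, kernel, kernel, kernel),
                                           cin * kernel ** 3))
        self.bias = Parameter(np.zeros((1, cout, 1, 1, 1))) if bias else None

    def forward(self, x):
        out = T.conv3d(x, self.weight, stride=self.stride, pad=self.pad)
        if self.bias is not None:
            out = out + self.bias
        return out


class ConvTranspose3d(Module):
    """Stride-2 kernel-2 transposed convolution: exact spatial doubling."""

    def __init__(self, cin, cout, kernel=2, stride=2, bias=True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.weight = Parameter(_he_normal(rng, (cin, cout, kernel, kernel, kernel),
                                           cin * kernel ** 3))
        self.bias = Parameter(np.zeros((1, cout, 1, 1, 1))) if bias else None

    def forward(self, x):
        out = T.conv_transpose3d(x, self.weight, stride=self.stride)
        if self.bias is not None:
            out = out + self.bias
        return out


class Linear(Module):
    def __init__(self, fin, fout, bias=True, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_normal(rng, (fin, fout), fin))
        self.bias = Parameter(np.zeros((fout,))) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups != 0:
            raise ValueError(f"groups={groups} must divide channels={channels}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        g = self.groups
        xg = T.reshape(x, (n, g, -1))
        mu = T.tmean(xg, axis=2, keepdims=True)
        d = xg - mu
        var = T.tmean(d * d, axis=2, keepdims=True)
        norm = d / T.sqrt(var + self.eps)
        norm = T.reshape(norm, (n, c) + spatial)
        return norm * self.gamma + self.beta


class LayerNorm(Module):
    """Normalizes over the last axis (token embeddings)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones((dim,)))
        self.beta = Parameter(np.zeros((dim,)))

    def forward(self, x):
        mu = T.tmean(x, axis=-1, keepdims=True)
        d = x - mu
        var = T.tmean(d * d, axis=-1, keepdims=True)
        return (d / T.sqrt(var + self.eps)) * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Dropout(Module):
    def __init__(self, p: float, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        return T.dropout(x, self.p, self.rng, self.training)


class SqueezeExcitation(Module):
    """Channel-attention block: global pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def forward(self, x):
        pooled = T.tmean(x, axis=(2, 3, 4))            # (N, C)
        gate = T.sigmoid(self.fc2(T.relu(self.fc1(pooled))))
        n, c = gate.shape
        return x * T.reshape(gate, (n, c, 1, 1, 1))


class MultiheadSelfAttention(Module):
    def __init__(self, embed_dim: int, heads: int, dropout: float = 0.0,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if embed_dim % heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        self.heads = heads
        self.head_dim = embed_dim // heads
        self.q_proj = Linear(embed_dim, embed_dim, rng=rng)
        self.k_proj = Linear(embed_dim, embed_dim, rng=rng)
        self.v_proj = Linear(embed_dim, embed_dim, rng=rng)
        self.out_proj = Linear(embed_dim, embed_dim, rng=rng)
        self.drop = Dropout(dropout, rng=rng)

    def forward(self, x):
        n, t, e = x.shape
        h, hd = self.heads, self.head_dim

        def split(z):  # (N, T, E) -> (N, H, T, hd)
            return T.transpose(T.reshape(z, (n, t, h, hd)), (0, 2, 1, 3))

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = (q @ T.transpose(k, (0, 1, 3, 2))) * (1.0 / math.sqrt(hd))
        attn = self.drop(T.softmax(scores, axis=-1))
        out = T.reshape(T.transpose(attn @ v, (0, 2, 1, 3)), (n, t, e))
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Pre-norm block: x + MHA(LN(x)); x + MLP(LN(x)); MLP width 4x."""

    def __init__(self, embed_dim: int, heads: int, mlp_ratio: int = 4,
                 dropout: float = 0.1, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.norm1 = LayerNorm(embed_dim)
        self.attn = MultiheadSelfAttention(embed_dim, heads, dropout=dropout, rng=rng)
        self.drop1 = Dropout(dropout, rng=rng)
        self.norm2 = LayerNorm(embed_dim)
        self.fc1 = Linear(embed_dim, mlp_ratio * embed_dim, rng=rng)
        self.fc2 = Linear(mlp_ratio * embed_dim, embed_dim, rng=rng)
        self.drop2 = Dropout(dropout, rng=rng)

    def forward(self, x):
        x = x + self.drop1(self.attn(self.norm1(x)))
        x = x + self.drop2(self.fc2(T.relu(self.fc1(self.norm2(x)))))
        return x


class TransformerEncoder(Module):
    def __init__(self, layers: int, embed_dim: int, heads: int,
                 dropout: float = 0.1, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.blocks = ModuleList(
            [TransformerEncoderLayer(embed_dim, heads, dropout=dropout, rng=rng)
             for _ in range(layers)]
        )
        self.final_norm = LayerNorm(embed_dim)

    def forward(self, x):
        for block in self.blocks:
            x = block(x)
        return self.final_norm(x)
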