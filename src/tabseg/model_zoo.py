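"""The segmentation network and its benchmark variants.

All variants share one encoder/decoder skeleton (same depth, same channel
schedule): five levels of double-convolution blocks with group normalization,
stride-2 convolution downsampling and transposed-convolution upsampling, with
U-Net skip concatenation. Variants toggle three ingredients:

- ``unet``     plain blocks
- ``unet_se``  squeeze-excitation gates before each downsampling
- ``resunet``  residual shortcuts around each block
- ``tabs``     resunet plus a transformer bottleneck: the deepest feature grid
               is tokenized (one token per spatial position, linear projection
               plus learned positional embedding), passed through a multi-head
               self-attention encoder, reshaped back and reduced to the
               bottleneck width by convolution.

The default geometry: a 192-voxel input, five levels (four halvings) down to a
12-voxel side with f=128 features; tokens are 12^3 = 1,728 positions of width
512, so the transformer works on a 512 x 1,728 value block. The output head is
a 1x1x1 convolution to 3 channels followed by a channel softmax, so per-voxel
tissue probabilities sum to 1.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .nn import layers as L
from .nn import tensor as T
from .nn.tensor import Tensor, no_grad
from .types import TissueProbMap

__all__ = [
    "ModelConfig",
    "SegmentationModel",
    "VARIANTS",
    "infer_bottleneck_shape",
    "build_model",
    "shape_trace",
    "tokenize",
    "transformer_encode",
    "detokenize",
    "forward",
]

VARIANTS = ("unet", "unet_se", "resunet", "tabs")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture variant plus every dimension of the network."""

    variant: str = "tabs"
    input_side: int = 192
    levels: int = 5
    bottleneck_features: int = 128
    channel_schedule: Optional[tuple[int, ...]] = None
    transformer_layers: int = 4
    transformer_heads: int = 8
    embed_dim: int = 512
    norm_groups: int = 8
    se_reduction: int = 16
    dropout: float = 0.1
    seed: int = 0

    def resolved_schedule(self) -> tuple[int, ...]:
        if self.channel_schedule is not None:
            return tuple(self.channel_schedule)
        f = self.bottleneck_features
        sched = tuple(f // 2 ** (self.levels - 1 - i) for i in range(self.levels))
        if sched[0] < 1 or sched[0] * 2 ** (self.levels - 1) != f:
            raise ValueError(
                "cannot derive a doubling channel schedule; pass channel_schedule"
            )
        return sched

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        halvings = 2 ** (self.levels - 1)
        if self.input_side % halvings != 0:
            raise ValueError(
                f"input_side={self.input_side} not divisible by 2^(levels-1)={halvings}"
            )
        if self.embed_dim % self.transformer_heads != 0:
            raise ValueError("embed_dim must be divisible by transformer_heads")
        sched = self.resolved_schedule()
        if len(sched) != self.levels:
            raise ValueError("channel_schedule must have `levels` entries")
        if sched[-1] != self.bottleneck_features:
            raise ValueError("channel_schedule must end at bottleneck_features")
        for c in sched:
            if c % self.norm_groups != 0:
                raise ValueError(
                    f"norm_groups={self.norm_groups} must divide every channel count {sched}"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        if d.get("channel_schedule") is not None:
            d["channel_schedule"] = tuple(d["channel_schedule"])
        return cls(**d)


def infer_bottleneck_shape(cfg: ModelConfig) -> tuple[int, int]:
    """(channels, spatial side) of the deepest encoder output."""
    cfg.validate()
    return cfg.bottleneck_features, cfg.input_side // 2 ** (cfg.levels - 1)


class ConvBlock(L.Module):
    """conv3-GN-ReLU-conv3-GN(-shortcut)-ReLU."""

    def __init__(self, cin, cout, groups, residual, rng):
        super().__init__()
        self.residual = residual
        self.conv1 = L.Conv3d(cin, cout, 3, rng=rng)
        self.gn1 = L.GroupNorm(groups, cout)
        self.conv2 = L.Conv3d(cout, cout, 3, rng=rng)
        self.gn2 = L.GroupNorm(groups, cout)
        if residual and cin != cout:
            self.shortcut = L.Conv3d(cin, cout, kernel=1, pad=0, bias=False, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x):
        h = T.relu(self.gn1(self.conv1(x)))
        h = self.gn2(self.conv2(h))
        if self.residual:
            h = h + (x if self.shortcut is None else self.shortcut(x))
        return T.relu(h)


class TransformerStage(L.Module):
    """Tokenize -> self-attention encoder -> detokenize, at the bottleneck."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        f, side = infer_bottleneck_shape(cfg)
        self.f = f
        self.side = side
        self.embed_dim = cfg.embed_dim
        self.n_tokens = side ** 3
        self.token_proj = L.Linear(f, cfg.embed_dim, rng=rng)
        self.pos_embed = L.Parameter(
            rng.normal(0.0, 0.02, size=(self.n_tokens, cfg.embed_dim))
        )
        self.encoder = L.TransformerEncoder(
            cfg.transformer_layers, cfg.embed_dim, cfg.transformer_heads,
            dropout=cfg.dropout, rng=rng,
        )
        self.reduce = L.Conv3d(cfg.embed_dim, f, 3, rng=rng)

    def tokenize(self, features: Tensor) -> Tensor:
        """(N, f, s, s, s) -> (N, s^3, embed): row-major spatial flattening,
        learned linear projection, learned additive positional embedding."""
        n = features.shape[0]
        if features.shape[1:] != (self.f, self.side, self.side, self.side):
            raise ValueError(
                f"expected features of shape (*, {self.f}, {self.side}^3), got {features.shape}"
            )
        flat = T.reshape(features, (n, self.f, self.n_tokens))
        tokens = T.transpose(flat, (0, 2, 1))        # (N, T, f)
        return self.token_proj(tokens) + self.pos_embed

    def encode(self, tokens: Tensor) -> Tensor:
        return self.encoder(tokens)

    def detokenize(self, tokens: Tensor) -> Tensor:
        """(N, s^3, embed) -> reshape to (N, embed, s, s, s) -> conv to f."""
        n, t, e = tokens.shape
        if t != self.n_tokens:
            raise ValueError(f"token count {t} is not the cube {self.n_tokens}")
        grid = T.reshape(T.transpose(tokens, (0, 2, 1)), (n, e, self.side, self.side, self.side))
        return self.reduce(grid)

    def forward(self, x):
        return self.detokenize(self.encode(self.tokenize(x)))


class SegmentationModel(L.Module):
    """Maps a 1-channel volume to a 3-channel tissue probability map."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        sched = cfg.resolved_schedule()
        residual = cfg.variant in ("resunet", "tabs")
        g = cfg.norm_groups

        self.enc_blocks = L.ModuleList(
            [ConvBlock(1, sched[0], g, residual, rng)]
            + [ConvBlock(sched[i], sched[i], g, residual, rng)
               for i in range(1, cfg.levels)]
        )
        if cfg.variant == "unet_se":
            self.se_blocks = L.ModuleList(
                [L.SqueezeExcitation(sched[i], cfg.se_reduction, rng=rng)
                 for i in range(cfg.levels - 1)]
            )
        else:
            self.se_blocks = None
        self.downs = L.ModuleList(
            [L.Conv3d(sched[i], sched[i + 1], 3, stride=2, pad=1, rng=rng)
             for i in range(cfg.levels - 1)]
        )
        if cfg.variant == "tabs":
            self.transformer_stage = TransformerStage(cfg, rng)
        else:
            self.transformer_stage = None
        self.ups = L.ModuleList(
            [L.ConvTranspose3d(sched[i + 1], sched[i], rng=rng)
             for i in range(cfg.levels - 1)]
        )
        self.dec_blocks = L.ModuleList(
            [ConvBlock(2 * sched[i], sched[i], g, residual, rng)
             for i in range(cfg.levels - 1)]
        )
        self.head = L.Conv3d(sched[0], 3, kernel=1, pad=0, rng=rng)

    def forward_logits(self, x: Tensor) -> Tensor:
        side = self.cfg.input_side
        if x.shape[2:] != (side, side, side) or x.shape[1] != 1:
            raise ValueError(f"expected input of shape (N, 1, {side}^3), got {x.shape}")
        h = self.enc_blocks[0](x)
        skips = []
        for i in range(self.cfg.levels - 1):
            if self.se_blocks is not None:
                h = self.se_blocks[i](h)
            skips.append(h)
            h = self.downs[i](h)
            h = self.enc_blocks[i + 1](h)
        if self.transformer_stage is not None:
            h = self.transformer_stage(h)
        for i in reversed(range(self.cfg.levels - 1)):
            h = self.ups[i](h)
            h = T.concat([h, skips[i]], axis=1)
            h = self.dec_blocks[i](h)
        return self.head(h)

    def forward(self, x: Tensor) -> Tensor:
        return T.softmax(self.forward_logits(x), axis=1)

    def predict_volume(self, values: np.ndarray) -> TissueProbMap:
        """Inference on one unbatched (D, D, D) array -> TissueProbMap."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                x = Tensor(np.asarray(values, dtype=np.float32)[None, None])
                probs = self.forward(x).data[0]
        finally:
            self.train(was_training)
        return TissueProbMap(probs)

    def parameter_shape_inventory(self) -> dict[str, tuple[int, ...]]:
        return {name: tuple(p.data.shape) for name, p in self.named_parameters()}


def build_model(cfg: ModelConfig) -> SegmentationModel:
    return SegmentationModel(cfg)


def shape_trace(cfg: ModelConfig) -> dict:
    """Arithmetic shape inference through every stage of the network."""
    cfg.validate()
    sched = cfg.resolved_schedule()
    f, side = infer_bottleneck_shape(cfg)
    sides = [cfg.input_side // 2 ** i for i in range(cfg.levels)]
    trace = {
        "input": (1, cfg.input_side, cfg.input_side, cfg.input_side),
        "encoder_levels": [(sched[i], sides[i], sides[i], sides[i]) for i in range(cfg.levels)],
        "bottleneck_channels": f,
        "bottleneck_side": side,
        "n_tokens": side ** 3,
        "embed_dim": cfg.embed_dim,
        # printed as (embedding channels x token positions)
        "transformer_output_block": (cfg.embed_dim, side ** 3),
        "detokenize_reshape": (cfg.embed_dim, side, side, side),
        "detokenize_reduced": (f, side, side, side),
        "output": (3, cfg.input_side, cfg.input_side, cfg.input_side),
    }
    return trace


# ---- unbatched functional surface (numpy in / numpy out) --------------------
def _bridge(model: SegmentationModel) -> TransformerStage:
    if model.transformer_stage is None:
        raise ValueError("model has no transformer stage (variant is not 'tabs')")
    return model.transformer_stage


def tokenize(model: SegmentationModel, features: np.ndarray) -> np.ndarray:
    """(f, s, s, s) bottleneck features -> (n_tokens, embed_dim) token matrix."""
    with no_grad():
        out = _bridge(model).tokenize(Tensor(features[None]))
    return out.data[0]


def transformer_encode(model: SegmentationModel, tokens: np.ndarray) -> np.ndarray:
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            out = _bridge(model).encode(Tensor(tokens[None]))
    finally:
        model.train(was_training)
    return out.data[0]


def detokenize(model: SegmentationModel, tokens: np.ndarray) -> np.ndarray:
    with no_grad():
        out = _bridge(model).detokenize(Tensor(tokens[None]))
    return out.data[0]


def forward(model: SegmentationModel, volume: np.ndarray) -> TissueProbMap:
    return model.predict_volume(volume)
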