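import numpy as np
import pytest

from conftest import tiny_cfg_variant
from tabseg.model_zoo import (
    ModelConfig,
    VARIANTS,
    build_model,
    detokenize,
    infer_bottleneck_shape,
    shape_trace,
    tokenize,
    transformer_encode,
)
from tabseg.nn.tensor import Tensor, no_grad


@pytest.mark.parametrize(
    "side,levels,f,expected",
    [(192, 5, 128, (128, 12)), (64, 5, 32, (32, 4)), (48, 3, 16, (16, 12))],
)
def test_infer_bottleneck_shape(side, levels, f, expected):
    cfg = ModelConfig(input_side=side, levels=levels, bottleneck_features=f,
                      embed_dim=64, transformer_heads=4, norm_groups=1)
    assert infer_bottleneck_shape(cfg) == expected


def test_default_config_geometry():
    cfg = ModelConfig()
    assert cfg.resolved_schedule() == (8, 16, 32, 64, 128)
    assert infer_bottleneck_shape(cfg) == (128, 12)
    trace = shape_trace(cfg)
    assert trace["n_tokens"] == 1728
    assert trace["transformer_output_block"] == (512, 1728)
    assert trace["detokenize_reshape"] == (512, 12, 12, 12)
    assert trace["detokenize_reduced"] == (128, 12, 12, 12)
    assert trace["output"] == (3, 192, 192, 192)


def test_config_validation_errors():
    with pytest.raises(ValueError):
        ModelConfig(variant="fastnet").validate()
    with pytest.raises(ValueError):
        ModelConfig(input_side=100).validate()  # not divisible by 16
    with pytest.raises(ValueError):
        ModelConfig(embed_dim=510).validate()  # heads must divide
    with pytest.raises(ValueError):
        ModelConfig(channel_schedule=(8, 16, 32, 64, 100)).validate()
    with pytest.raises(ValueError):
        ModelConfig(norm_groups=7).validate()


@pytest.mark.parametrize("variant", VARIANTS)
def test_forward_shape_and_softmax_contract(variant, rng):
    cfg = tiny_cfg_variant(variant)
    model = build_model(cfg).eval()
    x = Tensor(rng.standard_normal((1, 1, 16, 16, 16)).astype(np.float32))
    with no_grad():
        probs = model.forward(x).data
    assert probs.shape == (1, 3, 16, 16, 16)
    assert probs.min() > 0
    assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-5


def test_forward_rejects_wrong_input_shape(tiny_cfg):
    model = build_model(tiny_cfg)
    with pytest.raises(ValueError):
        model.forward(Tensor(np.zeros((1, 1, 8, 8, 8), np.float32)))


def test_seeded_init_bitwise_deterministic(tiny_cfg):
    m1 = build_model(tiny_cfg)
    m2 = build_model(tiny_cfg)
    for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
        assert n1 == n2
        assert np.array_equal(p1.data, p2.data)


def test_ablation_identity_tabs_minus_transformer_is_resunet():
    tabs = build_model(tiny_cfg_variant("tabs"))
    resunet = build_model(tiny_cfg_variant("resunet"))
    tabs_inv = tabs.parameter_shape_inventory()
    res_inv = resunet.parameter_shape_inventory()
    stripped = {k: v for k, v in tabs_inv.items() if not k.startswith("transformer_stage.")}
    assert stripped == res_inv
    # the two differ only by the transformer stage's parameters
    extra = {k for k in tabs_inv if k.startswith("transformer_stage.")}
    assert extra
    n_extra = sum(int(np.prod(tabs_inv[k])) for k in extra)
    assert tabs.n_parameters() - resunet.n_parameters() == n_extra


def test_variants_share_depth_and_channel_counts():
    inventories = {
        v: build_model(tiny_cfg_variant(v)).parameter_shape_inventory() for v in VARIANTS
    }
    # encoder block conv shapes agree across every variant
    for name, shape in inventories["unet"].items():
        if name.startswith("enc_blocks.") and ".conv" in name:
            for v in VARIANTS:
                assert inventories[v][name] == shape


def test_tokenize_shapes_and_positional_embedding(tiny_cfg, rng):
    model = build_model(tiny_cfg)
    f, s = infer_bottleneck_shape(tiny_cfg)
    feats = rng.standard_normal((f, s, s, s)).astype(np.float32)
    tokens = tokenize(model, feats)
    assert tokens.shape == (s ** 3, tiny_cfg.embed_dim)
    # one learned embedding per token position
    assert model.transformer_stage.pos_embed.data.shape == (s ** 3, tiny_cfg.embed_dim)


def test_tokenize_row_major_flattening(tiny_cfg, rng):
    # token k carries the feature vector at (k // s^2, (k // s) % s, k % s)
    model = build_model(tiny_cfg)
    f, s = infer_bottleneck_shape(tiny_cfg)
    feats = rng.standard_normal((f, s, s, s)).astype(np.float32)
    tokens = tokenize(model, feats)
    w = model.transformer_stage.token_proj.weight.data
    b = model.transformer_stage.token_proj.bias.data
    pos = model.transformer_stage.pos_embed.data
    for k in range(s ** 3):
        i, j, l = k // s ** 2, (k // s) % s, k % s
        expected = feats[:, i, j, l] @ w + b + pos[k]
        assert np.allclose(tokens[k], expected, atol=1e-5)


def test_transformer_encode_preserves_shape(tiny_cfg, rng):
    model = build_model(tiny_cfg)
    _, s = infer_bottleneck_shape(tiny_cfg)
    tokens = rng.standard_normal((s ** 3, tiny_cfg.embed_dim)).astype(np.float32)
    out = transformer_encode(model, tokens)
    assert out.shape == tokens.shape
    out2 = transformer_encode(model, tokens)
    assert np.array_equal(out, out2)  # deterministic in eval mode


def test_detokenize_shapes(tiny_cfg, rng):
    model = build_model(tiny_cfg)
    f, s = infer_bottleneck_shape(tiny_cfg)
    tokens = rng.standard_normal((s ** 3, tiny_cfg.embed_dim)).astype(np.float32)
    grid = detokenize(model, tokens)
    assert grid.shape == (f, s, s, s)
    with pytest.raises(ValueError):
        detokenize(model, tokens[:-1])


def test_detokenize_reshape_placement(rng):
    # embed == f lets a center-only identity kernel expose the reshape:
    # token k must land at spatial (k // s^2, (k // s) % s, k % s)
    cfg = tiny_cfg_variant("tabs", bottleneck_features=8, channel_schedule=(4, 4, 8),
                          embed_dim=8, transformer_heads=2)
    model = build_model(cfg)
    f, s = infer_bottleneck_shape(cfg)
    stage = model.transformer_stage
    w = np.zeros_like(stage.reduce.weight.data)
    for c in range(f):
        w[c, c, 1, 1, 1] = 1.0
    stage.reduce.weight.data = w
    stage.reduce.bias.data = np.zeros_like(stage.reduce.bias.data)
    tokens = rng.standard_normal((s ** 3, cfg.embed_dim)).astype(np.float32)
    grid = detokenize(model, tokens)
    for k in range(s ** 3):
        i, j, l = k // s ** 2, (k // s) % s, k % s
        assert np.allclose(grid[:, i, j, l], tokens[k], atol=1e-6)


def test_bottleneck_pipeline_matches_straightline_numpy_reference(tiny_cfg, rng):
    """tokenize -> encode -> detokenize against a from-scratch numpy replica
    using the same weights (layer norm, attention, MLP, reshape, conv)."""
    model = build_model(tiny_cfg).eval()
    stage = model.transformer_stage
    f, s = infer_bottleneck_shape(tiny_cfg)
    e = tiny_cfg.embed_dim
    heads = tiny_cfg.transformer_heads
    feats = rng.standard_normal((f, s, s, s)).astype(np.float32)

    actual = detokenize(model, transformer_encode(model, tokenize(model, feats)))

    def p(name):
        return dict(model.named_parameters())[f"transformer_stage.{name}"].data.astype(np.float64)

    def layer_norm(x, gamma, beta, eps=1e-5):
        mu = x.mean(-1, keepdims=True)
        var = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * gamma + beta

    tokens = feats.reshape(f, -1).T @ p("token_proj.weight") + p("token_proj.bias")
    tokens = tokens + p("pos_embed")
    hd = e // heads
    for li in range(tiny_cfg.transformer_layers):
        pre = f"encoder.blocks.m{li}."
        h = layer_norm(tokens, p(pre + "norm1.gamma"), p(pre + "norm1.beta"))
        q = (h @ p(pre + "attn.q_proj.weight") + p(pre + "attn.q_proj.bias"))
        k = (h @ p(pre + "attn.k_proj.weight") + p(pre + "attn.k_proj.bias"))
        v = (h @ p(pre + "attn.v_proj.weight") + p(pre + "attn.v_proj.bias"))
        t = tokens.shape[0]
        q = q.reshape(t, heads, hd).transpose(1, 0, 2)
        k = k.reshape(t, heads, hd).transpose(1, 0, 2)
        v = v.reshape(t, heads, hd).transpose(1, 0, 2)
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(hd)
        scores = np.exp(scores - scores.max(-1, keepdims=True))
        attn = scores / scores.sum(-1, keepdims=True)
        ctx = (attn @ v).transpose(1, 0, 2).reshape(t, e)
        ctx = ctx @ p(pre + "attn.out_proj.weight") + p(pre + "attn.out_proj.bias")
        tokens = tokens + ctx
        h = layer_norm(tokens, p(pre + "norm2.gamma"), p(pre + "norm2.beta"))
        h = np.maximum(h @ p(pre + "fc1.weight") + p(pre + "fc1.bias"), 0)
        tokens = tokens + (h @ p(pre + "fc2.weight") + p(pre + "fc2.bias"))
    tokens = layer_norm(tokens, p("encoder.final_norm.gamma"), p("encoder.final_norm.beta"))
    grid = tokens.T.reshape(e, s, s, s)
    gp = np.pad(grid, ((0, 0), (1, 1), (1, 1), (1, 1)))
    wr = p("reduce.weight")
    br = p("reduce.bias").ravel()
    expected = np.zeros((f, s, s, s))
    for c in range(f):
        for i in range(s):
            for j in range(s):
                for l in range(s):
                    expected[c, i, j, l] = (
                        np.sum(wr[c] * gp[:, i : i + 3, j : j + 3, l : l + 3]) + br[c]
                    )
    assert np.allclose(actual, expected, atol=1e-4)


def test_forward_softmax_matches_brute_force_on_logits(tiny_cfg, rng):
    model = build_model(tiny_cfg).eval()
    x = Tensor(rng.standard_normal((1, 1, 16, 16, 16)).astype(np.float32))
    with no_grad():
        logits = model.forward_logits(x).data
        probs = model.forward(x).data
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    assert np.allclose(probs, e / e.sum(axis=1, keepdims=True), atol=1e-6)


def test_uniform_logits_give_one_third():
    from tabseg.nn.tensor import softmax

    out = softmax(Tensor(np.zeros((1, 3, 2, 2, 2), np.float32)), axis=1).data
    assert np.allclose(out, 1.0 / 3.0)
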