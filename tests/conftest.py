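import numpy as np
import pytest

from tabseg.model_zoo import ModelConfig


def finite_difference_gradcheck(fn, *arrays, eps=1e-5, rtol=1e-3):
    """Compare analytic gradients of scalar fn(*Tensors) to central differences."""
    from tabseg.nn.tensor import Tensor

    tensors = [Tensor(a.astype(np.float64), requires_grad=True) for a in arrays]
    fn(*tensors).backward()
    for t in tensors:
        numeric = np.zeros_like(t.data)
        flat, nf = t.data.ravel(), numeric.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = fn(*tensors).item()
            flat[i] = orig - eps
            lm = fn(*tensors).item()
            flat[i] = orig
            nf[i] = (lp - lm) / (2 * eps)
        scale = max(1e-8, np.abs(numeric).max())
        assert np.abs(numeric - t.grad).max() / scale < rtol


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """Small tabs config for fast CPU forward passes (16^3 input)."""
    return ModelConfig(
        variant="tabs", input_side=16, levels=3, bottleneck_features=8,
        channel_schedule=(4, 4, 8), embed_dim=8, transformer_layers=1,
        transformer_heads=2, norm_groups=4, dropout=0.0, seed=11,
    )


def tiny_cfg_variant(variant, **overrides):
    base = dict(
        variant=variant, input_side=16, levels=3, bottleneck_features=8,
        channel_schedule=(4, 4, 8), embed_dim=8, transformer_layers=1,
        transformer_heads=2, norm_groups=4, dropout=0.0, seed=11,
    )
    base.update(overrides)
    return ModelConfig(**base)
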