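import numpy as np
import pytest

from dualattn import MINI, AttentionConfig, build_model
from dualattn.attention import init_attention_weights


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_attn():
    """A seeded dual-Key attention layer on a 14x14x8 map with 2 heads."""
    cfg = AttentionConfig(C=8, M=7, num_heads=2, variant="DA")
    wts = init_attention_weights(cfg, np.random.default_rng(42), std=0.2)
    x = np.random.default_rng(7).standard_normal((14, 14, 8))
    return x, wts, cfg


@pytest.fixture
def mini_model():
    return build_model(MINI, seed=0)
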