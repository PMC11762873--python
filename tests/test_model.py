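"""Backbone construction, layer contracts and checkpoint round trips."""

import dataclasses
import logging

import numpy as np
import pytest

from dualattn import (
    MINI,
    TINY,
    ModelConfig,
    build_model,
    classify,
    count_params,
    load_checkpoint,
    patch_embed,
    patch_merging,
    save_checkpoint,
    transformer_block,
)
from dualattn.autodiff import Tensor
from dualattn.model import BlockWeights
from dualattn.attention import AttentionConfig, init_attention_weights


# ----------------------------------------------------------------------
# config validation


def test_config_rejects_indivisible_heads():
    with pytest.raises(ValueError, match="not divisible by heads"):
        ModelConfig(embed_dim=30, heads=(4, 4, 4, 4))


def test_config_rejects_bad_input_size():
    with pytest.raises(ValueError, match="window"):
        ModelConfig(input_hw=(100, 100))  # 25-token grid, not divisible by 7


def test_stage_geometry_tiny():
    assert [TINY.stage_grid(s) for s in range(4)] == [(56, 56), (28, 28), (14, 14), (7, 7)]
    assert [TINY.stage_dim(s) for s in range(4)] == [96, 192, 384, 768]


# ----------------------------------------------------------------------
# patch embedding


def _embed_weights(rng, C=16, P=4):
    W = rng.standard_normal((P * P * 3, C)) * 0.1
    b = np.zeros(C)
    return W, b, np.ones(C), np.zeros(C)


def test_patch_embed_shapes_and_zero_input(rng):
    W, b, g, beta = _embed_weights(rng)
    out = patch_embed(np.zeros((8, 8, 3)), W, b, g, beta, 4)
    assert out.shape == (2, 2, 16)
    assert np.allclose(out, 0.0)  # zero map through zero bias stays zero


def test_patch_embed_matches_scalar_gather_oracle(rng):
    W, b, g, beta = _embed_weights(rng)
    x = rng.random((8, 8, 3))
    got = patch_embed(x, W, b, g, beta, 4)
    for pr in range(2):
        for pc in range(2):
            patch = x[pr * 4 : pr * 4 + 4, pc * 4 : pc * 4 + 4, :].reshape(-1)
            pre = patch @ W + b
            mu, var = pre.mean(), pre.var()
            expected = (pre - mu) / np.sqrt(var + 1e-5)
            assert np.allclose(got[pr, pc], expected, atol=1e-10)


def test_patch_embed_replicates_grayscale_with_warning(rng):
    W, b, g, beta = _embed_weights(rng)
    x = rng.random((8, 8, 1))
    with pytest.warns(UserWarning, match="grayscale"):
        out = patch_embed(x, W, b, g, beta, 4)
    assert out.shape == (2, 2, 16)


def test_patch_embed_pads_non_divisible_input(rng):
    W, b, g, beta = _embed_weights(rng)
    out = patch_embed(rng.random((9, 10, 3)), W, b, g, beta, 4)
    assert out.shape == (3, 3, 16)


# ----------------------------------------------------------------------
# patch merging


def test_patch_merging_shape_contract(rng):
    C = 4
    fm = rng.standard_normal((8, 6, C))
    out = patch_merging(fm, np.ones(4 * C), np.zeros(4 * C), rng.standard_normal((4 * C, 2 * C)))
    assert out.shape == (4, 3, 2 * C)


def test_patch_merging_constant_map_stays_constant(rng):
    C = 3
    W = rng.standard_normal((4 * C, 2 * C))
    out = patch_merging(np.full((4, 4, C), 2.0), np.ones(4 * C), np.zeros(4 * C), W)
    assert np.allclose(out, out[0, 0])


def test_patch_merging_matches_index_oracle(rng):
    C = 2
    fm = rng.standard_normal((4, 4, C))
    g, beta = rng.standard_normal(4 * C), rng.standard_normal(4 * C)
    W = rng.standard_normal((4 * C, 2 * C))
    got = patch_merging(fm, g, beta, W)
    for r in range(2):
        for c in range(2):
            block = fm[2 * r : 2 * r + 2, 2 * c : 2 * c + 2, :].reshape(-1)
            mu, var = block.mean(), block.var()
            normed = (block - mu) / np.sqrt(var + 1e-5) * g + beta
            assert np.allclose(got[r, c], normed @ W, atol=1e-10)


def test_patch_merging_rejects_odd_sides():
    with pytest.raises(ValueError, match="even"):
        patch_merging(np.zeros((5, 4, 2)), np.ones(8), np.zeros(8), np.zeros((8, 4)))


# ----------------------------------------------------------------------
# transformer block


def _zero_block(C, M, H, hidden):
    cfg = AttentionConfig(C=C, M=M, num_heads=H, variant="DA")
    attn = init_attention_weights(cfg, np.random.default_rng(0))
    for t in attn.named().values():
        t.data[:] = 0.0
    z = lambda *s: Tensor(np.zeros(s))
    o = lambda *s: Tensor(np.ones(s))
    return (
        BlockWeights(
            ln1_g=o(C), ln1_b=z(C), attn=attn, ln2_g=o(C), ln2_b=z(C),
            mlp_W1=z(C, hidden), mlp_b1=z(hidden), mlp_W2=z(hidden, C), mlp_b2=z(C),
        ),
        cfg,
    )


def test_zero_weight_block_is_identity(rng):
    bw, cfg = _zero_block(C=8, M=7, H=2, hidden=32)
    x = rng.standard_normal((14, 14, 8))
    assert np.array_equal(transformer_block(x, bw, cfg), x)


def test_block_matches_composed_oracle(rng):
    C, M, H = 8, 7, 2
    cfg = AttentionConfig(C=C, M=M, num_heads=H, variant="DA")
    attn = init_attention_weights(cfg, np.random.default_rng(3), std=0.2)
    hidden = 16
    r2 = np.random.default_rng(4)
    bw = BlockWeights(
        ln1_g=Tensor(r2.standard_normal(C)), ln1_b=Tensor(r2.standard_normal(C)),
        attn=attn,
        ln2_g=Tensor(r2.standard_normal(C)), ln2_b=Tensor(r2.standard_normal(C)),
        mlp_W1=Tensor(r2.standard_normal((C, hidden)) * 0.2),
        mlp_b1=Tensor(r2.standard_normal(hidden) * 0.1),
        mlp_W2=Tensor(r2.standard_normal((hidden, C)) * 0.2),
        mlp_b2=Tensor(r2.standard_normal(C) * 0.1),
    )
    x = rng.standard_normal((14, 14, C))
    got = transformer_block(x, bw, cfg)

    from scipy.special import erf

    from dualattn import attention_forward

    def ln(v, g, b):
        mu = v.mean(-1, keepdims=True)
        var = v.var(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + 1e-5) * g + b

    y = x + attention_forward(ln(x, bw.ln1_g.data, bw.ln1_b.data), attn, cfg)
    h = ln(y, bw.ln2_g.data, bw.ln2_b.data) @ bw.mlp_W1.data + bw.mlp_b1.data
    h = h * 0.5 * (1.0 + erf(h / np.sqrt(2.0)))
    expected = y + h @ bw.mlp_W2.data + bw.mlp_b2.data
    assert np.allclose(got, expected, atol=1e-10)


# ----------------------------------------------------------------------
# whole model


@pytest.mark.parametrize("variant", ["WMSA", "DA_N", "DA"])
def test_instantiated_count_matches_shape_audit(variant):
    cfg = dataclasses.replace(MINI, variant=variant)
    assert build_model(cfg, 0).n_params() == count_params(cfg)


def test_four_stage_small_model_count_matches_audit():
    cfg = ModelConfig(
        patch_size=4, embed_dim=16, depths=(1, 1, 1, 1), heads=(1, 2, 4, 8),
        M=2, input_hw=(64, 64), num_classes=3,
    )
    assert build_model(cfg, 1).n_params() == count_params(cfg)


def test_same_seed_gives_bit_identical_weights():
    a, b = build_model(MINI, 5), build_model(MINI, 5)
    for k, t in a.parameters().items():
        assert np.array_equal(t.data, b.parameters()[k].data)
    c = build_model(MINI, 6)
    assert any(
        not np.array_equal(t.data, c.parameters()[k].data)
        for k, t in a.parameters().items()
    )


def test_dual_key_variants_share_parameter_count():
    assert count_params(dataclasses.replace(MINI, variant="DA")) == count_params(
        dataclasses.replace(MINI, variant="DA_N")
    )


def test_classify_outputs_probabilities(mini_model, rng):
    imgs = rng.random((3, 56, 56, 3))
    probs = classify(mini_model, imgs)
    assert probs.shape == (3, 2)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    dup = classify(mini_model, np.stack([imgs[0], imgs[0]]))
    assert np.allclose(dup[0], dup[1])


def test_classify_is_batch_order_equivariant(mini_model, rng):
    imgs = rng.random((4, 56, 56, 3))
    p = classify(mini_model, imgs)
    perm = [2, 0, 3, 1]
    assert np.allclose(classify(mini_model, imgs[perm]), p[perm], atol=1e-10)


def test_classify_empty_batch(mini_model):
    assert classify(mini_model, np.zeros((0, 56, 56, 3))).shape == (0, 2)


def test_checkpoint_round_trip_and_skip_logging(tmp_path, caplog):
    da = build_model(MINI, 0)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(da, path)

    da2 = build_model(MINI, 1)
    skipped = load_checkpoint(da2, path)
    assert skipped == []
    for k, t in da.parameters().items():
        assert np.array_equal(t.data, da2.parameters()[k].data)

    wmsa = build_model(dataclasses.replace(MINI, variant="WMSA"), 0)
    with caplog.at_level(logging.WARNING):
        skipped = load_checkpoint(wmsa, path)
    assert any("W_K2" in s for s in skipped)
    assert any("skipped" in r.message for r in caplog.records)
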