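"""Window bookkeeping, score fusion, forward pass and gradient paths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualattn import (
    AttentionConfig,
    attention_forward,
    cyclic_shift,
    da_scores,
    gradcheck,
    standard_scores,
    window_partition,
    window_reverse,
)
from dualattn.attention import AttentionWeights, init_attention_weights, relative_position_index


# ----------------------------------------------------------------------
# cyclic shift


def test_cyclic_shift_zero_and_full_period_are_identity(rng):
    x = rng.standard_normal((6, 8, 2))
    assert np.array_equal(cyclic_shift(x, (0, 0)), x)
    assert np.array_equal(cyclic_shift(x, (6, 8)), x)


def test_cyclic_shift_modular_indexing():
    x = np.arange(16.0).reshape(4, 4, 1)
    out = cyclic_shift(x, (2, 2))
    # out[r, c] = in[(r+2) % 4, (c+2) % 4]
    assert out[0, 0, 0] == 10.0
    for r in range(4):
        for c in range(4):
            assert out[r, c, 0] == x[(r + 2) % 4, (c + 2) % 4, 0]


@given(
    h=st.integers(1, 8),
    w=st.integers(1, 8),
    dr=st.integers(-10, 10),
    dc=st.integers(-10, 10),
    seed=st.integers(0, 10),
)
@settings(max_examples=40, deadline=None)
def test_cyclic_shift_inverts_exactly(h, w, dr, dc, seed):
    x = np.random.default_rng(seed).standard_normal((h, w, 2))
    assert np.array_equal(cyclic_shift(cyclic_shift(x, (dr, dc)), (-dr, -dc)), x)


# ----------------------------------------------------------------------
# window partition / reverse


def test_single_window_is_flattened_input(rng):
    x = rng.standard_normal((7, 7, 3))
    ws = window_partition(x, 7)
    assert ws.shape == (1, 49, 3)
    assert np.array_equal(ws[0], x.reshape(49, 3))


def test_window_ordering_is_row_major():
    x = np.random.default_rng(1).standard_normal((14, 14, 2))
    ws = window_partition(x, 7)
    assert ws.shape == (4, 49, 2)
    # window 3 is the bottom-right tile; its position 0 is input[7, 7]
    assert np.array_equal(ws[3, 0], x[7, 7])
    assert np.array_equal(ws[1, 0], x[0, 7])
    assert np.array_equal(ws[2, 48], x[13, 6])


@given(
    nh=st.integers(1, 4),
    nw=st.integers(1, 4),
    M=st.integers(1, 5),
    seed=st.integers(0, 100),
)
@settings(max_examples=40, deadline=None)
def test_window_round_trip_is_exact(nh, nw, M, seed):
    x = np.random.default_rng(seed).standard_normal((nh * M, nw * M, 3))
    assert np.array_equal(window_reverse(window_partition(x, M), nh * M, nw * M), x)


def test_window_round_trip_28x28x3_bit_exact(rng):
    x = rng.standard_normal((28, 28, 3))
    assert np.array_equal(window_reverse(window_partition(x, 7), 28, 28), x)


def test_constant_windows_reverse_to_constant_map():
    ws = np.full((4, 49, 2), 3.25)
    fm = window_reverse(ws, 14, 14)
    assert (fm == 3.25).all()


def test_window_partition_rejects_non_divisible():
    with pytest.raises(ValueError, match="M=7.*h=15|h=15.*M=7"):
        window_partition(np.zeros((15, 14, 1)), 7)


def test_window_reverse_rejects_inconsistent_shape():
    with pytest.raises(ValueError):
        window_reverse(np.zeros((3, 49, 2)), 14, 14)


# ----------------------------------------------------------------------
# scores


def test_zero_query_gives_uniform_rows():
    A = standard_scores(np.zeros((4, 2)), np.random.default_rng(0).standard_normal((4, 2)), 2)
    assert np.allclose(A, 0.25)


def test_two_position_scores_match_scalar_softmax():
    # pre-softmax row 0 of Q K^T / sqrt(1) is (1, 0)
    A = standard_scores(np.array([[1.0], [0.0]]), np.array([[1.0], [0.0]]), 1)
    e = math.e
    assert np.allclose(A[0], [e / (e + 1), 1 / (e + 1)])
    assert np.allclose(A[1], [0.5, 0.5])


def test_score_rows_sum_to_one(rng):
    Q, K1, K2 = (rng.standard_normal((9, 4)) for _ in range(3))
    for A in (standard_scores(Q, K1, 4), da_scores(Q, K1, K2, 4)):
        assert np.allclose(A.sum(axis=-1), 1.0, atol=1e-6)
        assert (A >= 0).all() and (A <= 1).all()


def test_zero_second_key_reduces_to_single_key(rng):
    Q, K = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
    assert np.allclose(da_scores(Q, K, np.zeros_like(K), 3), standard_scores(Q, K, 3))


def test_tied_keys_double_the_score(rng):
    Q, K = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
    expected = standard_scores(Q, 2.0 * K, 3)  # softmax(2 Q K^T / sqrt(d_k))
    assert np.allclose(da_scores(Q, K, K, 3), expected, atol=1e-12)


def test_da_scores_match_scalar_loop_oracle():
    rng = np.random.default_rng(11)
    Q, K1, K2 = (rng.standard_normal((4, 2)) for _ in range(3))
    got = da_scores(Q, K1, K2, 2)
    # brute-force: element-by-element score fusion and row softmax
    expected = np.zeros((4, 4))
    for i in range(4):
        row = []
        for j in range(4):
            s = sum(Q[i, d] * K1[j, d] for d in range(2)) / math.sqrt(2)
            s += sum(Q[i, d] * K2[j, d] for d in range(2)) / math.sqrt(2)
            row.append(s)
        mx = max(row)
        exps = [math.exp(v - mx) for v in row]
        expected[i] = np.array(exps) / sum(exps)
    assert np.allclose(got, expected, atol=1e-6)


def test_scores_reject_bad_inputs(rng):
    Q = rng.standard_normal((4, 2))
    with pytest.raises(ValueError):
        standard_scores(np.full((4, 2), np.nan), Q, 2)
    with pytest.raises(ValueError):
        da_scores(Q, Q, rng.standard_normal((5, 2)), 2)
    with pytest.raises(ValueError):
        standard_scores(Q, Q, 0)


# ----------------------------------------------------------------------
# forward pass


def _brute_force_attention(x, wts, cfg):
    """Scalar-style reference: loops over windows, heads and positions."""
    h, w, C = x.shape
    M, H, dk = cfg.M, cfg.num_heads, cfg.d_k

    def proj(src, W, b):
        out = src.reshape(-1, C) @ np.asarray(W.data if hasattr(W, "data") else W)
        if b is not None:
            out = out + np.asarray(b.data if hasattr(b, "data") else b)
        return out.reshape(h, w, C)

    g = lambda t: np.asarray(t.data if hasattr(t, "data") else t)
    q = proj(x, wts.W_Q, wts.b_Q)
    k1 = proj(x, wts.W_K1, wts.b_K1)
    v = proj(x, wts.W_V, wts.b_V)
    if cfg.variant == "DA":
        src = np.roll(x, (-(M // 2), -(M // 2)), axis=(0, 1))
    else:
        src = x
    k2 = proj(src, wts.W_K2, wts.b_K2) if cfg.variant != "WMSA" else None
    relidx = relative_position_index(M)
    table = g(wts.relpos_table) if cfg.use_relpos and wts.relpos_table is not None else None
    out = np.zeros_like(x)
    for wr in range(h // M):
        for wc in range(w // M):
            rows = slice(wr * M, wr * M + M)
            cols = slice(wc * M, wc * M + M)
            Qw = q[rows, cols].reshape(M * M, C)
            K1w = k1[rows, cols].reshape(M * M, C)
            Vw = v[rows, cols].reshape(M * M, C)
            K2w = k2[rows, cols].reshape(M * M, C) if k2 is not None else None
            merged = np.zeros((M * M, C))
            for hd in range(H):
                sl = slice(hd * dk, (hd + 1) * dk)
                pre = Qw[:, sl] @ K1w[:, sl].T / math.sqrt(dk)
                if K2w is not None:
                    pre = pre + Qw[:, sl] @ K2w[:, sl].T / math.sqrt(dk)
                if table is not None:
                    pre = pre + table[relidx, hd]
                pre = pre - pre.max(axis=-1, keepdims=True)
                A = np.exp(pre) / np.exp(pre).sum(axis=-1, keepdims=True)
                merged[:, sl] = A @ Vw[:, sl]
            out[rows, cols] = merged.reshape(M, M, C)
    out = out.reshape(-1, C) @ g(wts.W_out)
    if wts.b_out is not None:
        out = out + g(wts.b_out)
    return out.reshape(h, w, C)


def test_forward_matches_brute_force_oracle(small_attn):
    x, wts, cfg = small_attn
    got = attention_forward(x, wts, cfg)
    expected = _brute_force_attention(x, wts, cfg)
    assert np.allclose(got, expected, atol=1e-5)
    assert got.shape == x.shape


def test_forward_oracle_agreement_without_relpos():
    cfg = AttentionConfig(C=8, M=7, num_heads=2, variant="DA", use_relpos=False)
    wts = init_attention_weights(cfg, np.random.default_rng(5), std=0.3)
    x = np.random.default_rng(6).standard_normal((14, 14, 8))
    assert np.allclose(
        attention_forward(x, wts, cfg), _brute_force_attention(x, wts, cfg), atol=1e-5
    )


def test_zero_k2_reduces_to_wmsa_bit_exact():
    rng = np.random.default_rng(9)
    cfg_da = AttentionConfig(C=8, M=7, num_heads=2, variant="DA")
    wts = init_attention_weights(cfg_da, rng, std=0.2)
    wts.W_K2.data[:] = 0.0
    wts.b_K2.data[:] = 0.0
    x = rng.standard_normal((14, 14, 8))
    out_da = attention_forward(x, wts, cfg_da)

    cfg_w = AttentionConfig(C=8, M=7, num_heads=2, variant="WMSA")
    wts_w = AttentionWeights(
        W_Q=wts.W_Q, W_K1=wts.W_K1, W_V=wts.W_V, W_out=wts.W_out,
        b_Q=wts.b_Q, b_K1=wts.b_K1, b_V=wts.b_V, b_out=wts.b_out,
        relpos_table=wts.relpos_table,
    )
    out_w = attention_forward(x, wts_w, cfg_w)
    assert np.array_equal(out_da, out_w)


def test_tied_k2_equals_doubled_key_baseline():
    # DA_N with W_K2 = W_K1 has pre-softmax score 2 Q K1^T / sqrt(d_k),
    # identical (in exact IEEE arithmetic) to a single Key of doubled weights
    rng = np.random.default_rng(10)
    cfg_dn = AttentionConfig(C=8, M=7, num_heads=2, variant="DA_N")
    wts = init_attention_weights(cfg_dn, rng, std=0.2)
    wts.W_K2.data = wts.W_K1.data.copy()
    wts.b_K2.data = wts.b_K1.data.copy()
    x = rng.standard_normal((14, 14, 8))
    out_dn = attention_forward(x, wts, cfg_dn)

    cfg_w = AttentionConfig(C=8, M=7, num_heads=2, variant="WMSA")
    from dualattn.autodiff import Tensor

    wts_w = AttentionWeights(
        W_Q=wts.W_Q, W_K1=Tensor(2.0 * wts.W_K1.data), W_V=wts.W_V, W_out=wts.W_out,
        b_Q=wts.b_Q, b_K1=Tensor(2.0 * wts.b_K1.data), b_V=wts.b_V, b_out=wts.b_out,
        relpos_table=wts.relpos_table,
    )
    assert np.array_equal(out_dn, attention_forward(x, wts_w, cfg_w))


def test_forward_configuration_errors(small_attn):
    x, wts, cfg = small_attn
    cfg_w = AttentionConfig(C=8, M=7, num_heads=2, variant="WMSA")
    with pytest.raises(ValueError, match="W_K2"):
        attention_forward(x, wts, cfg_w)
    with pytest.raises(ValueError, match="does not divide"):
        attention_forward(np.zeros((15, 14, 8)), wts, cfg)


def test_attention_config_invariants():
    with pytest.raises(ValueError, match="divisible"):
        AttentionConfig(C=7, M=7, num_heads=2)
    with pytest.raises(ValueError, match="variant"):
        AttentionConfig(C=8, M=7, num_heads=2, variant="SWIN")
    assert AttentionConfig(C=8, M=7, num_heads=2).d_k == 4


# ----------------------------------------------------------------------
# gradient verification


def test_gradcheck_linear_hook_is_near_exact():
    rep = gradcheck("linear", seed=0, eps=1e-4)
    assert rep.max_rel_dev <= 1e-8


@pytest.mark.parametrize("op", ["standard_scores", "da_scores"])
def test_gradcheck_scores_below_tolerance(op):
    rep = gradcheck(op, seed=0, eps=1e-4)
    assert 0.0 <= rep.max_rel_dev < 1e-3


def test_gradcheck_attention_confirms_dual_path():
    rep = gradcheck("attention_forward", seed=0, eps=1e-4)
    assert rep.max_rel_dev < 1e-3
    # blocking either Key path must leave a nonzero Query gradient (the
    # summed score has two live gradient routes into Q)
    assert rep.dual_path_ok is True


def test_gradcheck_rejects_bad_eps_and_op():
    with pytest.raises(ValueError):
        gradcheck("da_scores", eps=1e-2)
    with pytest.raises(ValueError):
        gradcheck("unknown_op")
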