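"""Double-attention (dual-Key) window self-attention core.

Window attention restricts multi-head self-attention to non-overlapping
M x M token windows.  The double-attention (DA) variant adds a second Key
matrix, K2, projected from a cyclically shifted copy of the feature map;
its pre-softmax score is

    A_DA = softmax( Q K1^T / sqrt(d_k) + Q K2^T / sqrt(d_k) )

so that query/key pairs that sit in different windows of the unshifted map
contribute to every attention layer, replacing the alternating
shifted-window scheme.  ``DA_N`` is the ablation in which K2 is projected
from the *unshifted* map (extra width, no cross-window flow); ``WMSA`` is
the plain single-Key window attention baseline.

All functions accept either plain NumPy arrays or autodiff ``Tensor``s and
return the same kind; the model layer passes Tensors so the whole forward
pass is differentiable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .autodiff import Tensor, softmax as _softmax

__all__ = [
    "Variant",
    "ShiftOffsets",
    "AttentionConfig",
    "AttentionWeights",
    "cyclic_shift",
    "window_partition",
    "window_reverse",
    "standard_scores",
    "da_scores",
    "attention_forward",
    "relative_position_index",
    "init_attention_weights",
    "gradcheck",
    "GradCheckReport",
]

Variant = Literal["WMSA", "DA_N", "DA"]
VARIANTS = ("WMSA", "DA_N", "DA")


@dataclass(frozen=True)
class ShiftOffsets:
    """Cyclic shift offsets (rows, cols); applied modulo the map size."""

    dr: int
    dc: int


def default_shift(M: int) -> ShiftOffsets:
    """The half-window shift used to source K2: floor(M/2) in both axes."""
    return ShiftOffsets(M // 2, M // 2)


@dataclass(frozen=True)
class AttentionConfig:
    """Hyperparameters of one window-attention layer.

    ``d_k`` (per-head key dimension) is always ``C / num_heads``.
    """

    C: int
    M: int
    num_heads: int
    variant: Variant = "DA"
    use_bias: bool = True
    use_relpos: bool = True

    def __post_init__(self):
        if self.C < 1 or self.M < 1 or self.num_heads < 1:
            raise ValueError("C, M and num_heads must be positive")
        if self.C % self.num_heads != 0:
            raise ValueError(
                f"channel count C={self.C} is not divisible by num_heads={self.num_heads}"
            )
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")

    @property
    def d_k(self) -> int:
        return self.C // self.num_heads


@dataclass
class AttentionWeights:
    """Learned projections of one attention layer.

    ``W_K2`` is present iff the variant uses a second Key; ``relpos_table``
    has shape ((2M-1)^2, num_heads) and is indexed by the relative offset
    of each in-window position pair.
    """

    W_Q: object
    W_K1: object
    W_V: object
    W_out: object
    W_K2: object = None
    b_Q: object = None
    b_K1: object = None
    b_K2: object = None
    b_V: object = None
    b_out: object = None
    relpos_table: object = None

    def named(self) -> dict:
        out = {}
        for name in (
            "W_Q", "W_K1", "W_K2", "W_V", "W_out",
            "b_Q", "b_K1", "b_K2", "b_V", "b_out", "relpos_table",
        ):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


# ----------------------------------------------------------------------
# window bookkeeping


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def cyclic_shift(fm, off: ShiftOffsets | tuple[int, int]):
    """Cyclically shift a feature map: out[r, c] = in[(r+dr) % h, (c+dc) % w].

    Operates on the two spatial axes of an (..., h, w, C) array; offsets of
    any sign wrap around, so applying the negated offsets restores the
    input exactly.
    """
    if isinstance(off, tuple):
        off = ShiftOffsets(*off)
    if isinstance(fm, Tensor):
        return fm.roll((-off.dr, -off.dc), axis=(-3, -2))
    return np.roll(np.asarray(fm), (-off.dr, -off.dc), axis=(-3, -2))


def window_partition(fm, M: int):
    """Tile an (..., h, w, C) map into (..., n_windows, M*M, C) windows.

    Windows are ordered row-major over the tiling and positions row-major
    within each window; :func:`window_reverse` is its exact inverse.
    """
    shape = fm.shape
    h, w, C = shape[-3], shape[-2], shape[-1]
    if h % M or w % M:
        raise ValueError(f"window size M={M} does not divide feature map h={h}, w={w}")
    lead = shape[:-3]
    nh, nw = h // M, w // M
    x = fm.reshape(lead + (nh, M, nw, M, C))
    ax = len(lead)
    x = x.transpose(tuple(range(ax)) + (ax, ax + 2, ax + 1, ax + 3, ax + 4))
    return x.reshape(lead + (nh * nw, M * M, C))


def window_reverse(ws, h: int, w: int):
    """Invert :func:`window_partition` back to an (..., h, w, C) map."""
    shape = ws.shape
    n_windows, mm, C = shape[-3], shape[-2], shape[-1]
    M = int(round(math.sqrt(mm)))
    if M * M != mm or n_windows * mm != h * w:
        raise ValueError(
            f"cannot assemble {n_windows} windows of {mm} positions into an {h}x{w} map"
        )
    lead = shape[:-3]
    nh, nw = h // M, w // M
    x = ws.reshape(lead + (nh, nw, M, M, C))
    ax = len(lead)
    x = x.transpose(tuple(range(ax)) + (ax, ax + 2, ax + 1, ax + 3, ax + 4))
    return x.reshape(lead + (h, w, C))


# ----------------------------------------------------------------------
# attention scores


def _check_finite(name: str, x) -> None:
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    if not np.isfinite(data).all():
        raise ValueError(f"{name} contains non-finite values")


def standard_scores(Qw, Kw, d_k: int):
    """Single-Key attention scores: row-wise softmax of Q K^T / sqrt(d_k)."""
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    _check_finite("Qw", Qw)
    _check_finite("Kw", Kw)
    tensor_in = _is_tensor(Qw, Kw)
    Q, K = Tensor(Qw) if not isinstance(Qw, Tensor) else Qw, (
        Tensor(Kw) if not isinstance(Kw, Tensor) else Kw
    )
    A = _softmax((Q @ K.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k)), axis=-1)
    return A if tensor_in else A.data


def da_scores(Qw, K1w, K2w, d_k: int):
    """Dual-Key scores: softmax of (Q K1^T + Q K2^T) / sqrt(d_k).

    Both score terms share the single 1/sqrt(d_k) scale before the
    addition; the softmax is applied once to the sum.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    for name, x in (("Qw", Qw), ("K1w", K1w), ("K2w", K2w)):
        _check_finite(name, x)
    if tuple(K1w.shape) != tuple(K2w.shape):
        raise ValueError(f"K1w shape {tuple(K1w.shape)} != K2w shape {tuple(K2w.shape)}")
    tensor_in = _is_tensor(Qw, K1w, K2w)
    Q = Qw if isinstance(Qw, Tensor) else Tensor(Qw)
    K1 = K1w if isinstance(K1w, Tensor) else Tensor(K1w)
    K2 = K2w if isinstance(K2w, Tensor) else Tensor(K2w)
    scale = 1.0 / math.sqrt(d_k)
    pre = (Q @ K1.swapaxes(-1, -2)) * scale + (Q @ K2.swapaxes(-1, -2)) * scale
    A = _softmax(pre, axis=-1)
    return A if tensor_in else A.data


def relative_position_index(M: int) -> np.ndarray:
    """(M^2, M^2) index into the (2M-1)^2-row relative-position bias table."""
    coords = np.stack(np.meshgrid(np.arange(M), np.arange(M), indexing="ij"))  # 2,M,M
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # 2, M^2, M^2
    rel = rel + (M - 1)
    return rel[0] * (2 * M - 1) + rel[1]


# ----------------------------------------------------------------------
# multi-head forward pass


def _project(x: Tensor, W, b):
    W = W if isinstance(W, Tensor) else Tensor(W)
    out = x @ W
    if b is not None:
        out = out + (b if isinstance(b, Tensor) else Tensor(b))
    return out


def _split_heads(x: Tensor, H: int, d_k: int):
    # (..., nW, M^2, C) -> (..., nW, H, M^2, d_k)
    lead = x.shape[:-1]
    x = x.reshape(lead + (H, d_k))
    return x.swapaxes(-3, -2)


def attention_forward(x, wts: AttentionWeights, cfg: AttentionConfig, *, _block_path=None):
    """Multi-head window attention over an (..., h, w, C) feature map.

    Q, K1 and V are projected from ``x``; K2 is projected from the
    half-window cyclic shift of ``x`` (variant ``DA``) or from ``x``
    itself (``DA_N``), and is absent for ``WMSA``.  Scores follow
    :func:`da_scores` (or :func:`standard_scores`), with the
    relative-position bias added to the pre-softmax sum when enabled.

    ``_block_path`` ('k1' or 'k2') detaches one score term from the
    autodiff graph; it exists solely for gradient-path diagnostics.
    """
    if cfg.variant == "WMSA" and wts.W_K2 is not None:
        raise ValueError("variant WMSA does not take a W_K2 projection")
    if cfg.variant in ("DA", "DA_N") and wts.W_K2 is None:
        raise ValueError(f"variant {cfg.variant} requires a W_K2 projection")

    tensor_in = isinstance(x, Tensor)
    xt = x if tensor_in else Tensor(np.asarray(x))
    h, w, C = xt.shape[-3], xt.shape[-2], xt.shape[-1]
    if C != cfg.C:
        raise ValueError(f"feature map has C={C} channels but config expects {cfg.C}")
    M, H, d_k = cfg.M, cfg.num_heads, cfg.d_k
    scale = 1.0 / math.sqrt(d_k)

    q = _project(xt, wts.W_Q, wts.b_Q)
    k1 = _project(xt, wts.W_K1, wts.b_K1)
    v = _project(xt, wts.W_V, wts.b_V)
    Qw = _split_heads(window_partition(q, M), H, d_k)
    K1w = _split_heads(window_partition(k1, M), H, d_k)
    Vw = _split_heads(window_partition(v, M), H, d_k)

    pre = (Qw @ K1w.swapaxes(-1, -2)) * scale
    if _block_path == "k1":
        pre = pre.detach()
    if cfg.variant in ("DA", "DA_N"):
        src = cyclic_shift(xt, default_shift(M)) if cfg.variant == "DA" else xt
        k2 = _project(src, wts.W_K2, wts.b_K2)
        K2w = _split_heads(window_partition(k2, M), H, d_k)
        term2 = (Qw @ K2w.swapaxes(-1, -2)) * scale
        if _block_path == "k2":
            term2 = term2.detach()
        pre = pre + term2

    if cfg.use_relpos and wts.relpos_table is not None:
        table = (
            wts.relpos_table
            if isinstance(wts.relpos_table, Tensor)
            else Tensor(wts.relpos_table)
        )
        idx = relative_position_index(M)
        bias = table.take(idx)  # (M^2, M^2, H)
        pre = pre + bias.transpose(2, 0, 1)  # broadcast over (..., nW, H, ., .)

    A = _softmax(pre, axis=-1)
    out = A @ Vw  # (..., nW, H, M^2, d_k)
    out = out.swapaxes(-3, -2).reshape(out.shape[:-3] + (M * M, C))
    out = window_reverse(out, h, w)
    out = _project(out, wts.W_out, wts.b_out)
    return out if tensor_in else out.data


# ----------------------------------------------------------------------
# weight construction


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal at +/- 2 std, the usual transformer initializer."""
    x = rng.standard_normal(shape) * std
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.standard_normal(bad.sum()) * std
        bad = np.abs(x) > 2 * std
    return x


def init_attention_weights(
    cfg: AttentionConfig, rng: np.random.Generator, std: float = 0.02
) -> AttentionWeights:
    """Seeded initialization: truncated-normal projections, zero biases."""
    C = cfg.C

    def mat():
        return Tensor(trunc_normal(rng, (C, C), std), requires_grad=True)

    def vec():
        return Tensor(np.zeros(C), requires_grad=True)

    wts = AttentionWeights(W_Q=mat(), W_K1=mat(), W_V=mat(), W_out=mat())
    if cfg.use_bias:
        wts.b_Q, wts.b_K1, wts.b_V, wts.b_out = vec(), vec(), vec(), vec()
    if cfg.variant in ("DA", "DA_N"):
        wts.W_K2 = mat()
        if cfg.use_bias:
            wts.b_K2 = vec()
    if cfg.use_relpos:
        wts.relpos_table = Tensor(
            trunc_normal(rng, ((2 * cfg.M - 1) ** 2, cfg.num_heads), std),
            requires_grad=True,
        )
    return wts


# ----------------------------------------------------------------------
# finite-difference gradient verification


@dataclass
class GradCheckReport:
    """Outcome of a finite-difference check of the autodiff gradients."""

    op_id: str
    max_rel_dev: float
    n_scalars: int
    dual_path_ok: bool | None = None  # DA only: dL/dW_Q nonzero via each Key path
    seed: int = 0


def _has_score_ties(pre: np.ndarray) -> bool:
    srt = np.sort(pre.reshape(-1, pre.shape[-1]), axis=-1)
    return bool((np.diff(srt, axis=-1) == 0.0).any())


def _fd_max_dev(fn, tensors: list[Tensor], eps: float) -> tuple[float, int]:
    loss = fn()
    loss.backward()
    analytic = [t.grad.copy() if t.grad is not None else np.zeros_like(t.data) for t in tensors]
    max_dev = 0.0
    n = 0
    for t, g in zip(tensors, analytic):
        flat = t.data.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = fn().data.item()
            flat[i] = orig - eps
            lm = fn().data.item()
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            dev = abs(gflat[i] - numeric) / (abs(gflat[i]) + eps)
            max_dev = max(max_dev, dev)
            n += 1
    return max_dev, n


def gradcheck(op_id: str, seed: int = 0, eps: float = 1e-4) -> GradCheckReport:
    """Verify autodiff gradients of an attention operation by central
    finite differences, returning the max relative deviation over every
    learnable scalar.

    For ``attention_forward`` (variant DA) the report also confirms the
    dual gradient path of the summed score: the loss gradient w.r.t. W_Q
    stays nonzero when either single Key path is blocked.
    """
    if not (1e-6 <= eps <= 1e-3):
        raise ValueError("eps must lie in [1e-6, 1e-3]")
    rng = np.random.default_rng(seed)

    if op_id == "linear":
        X = Tensor(rng.standard_normal((4, 3)), requires_grad=True)
        W = Tensor(rng.standard_normal((3, 5)), requires_grad=True)
        dev, n = _fd_max_dev(lambda: (X @ W).sum(), [X, W], eps)
        return GradCheckReport(op_id, dev, n, seed=seed)

    if op_id in ("standard_scores", "da_scores"):
        d_k = 2
        mk = lambda: Tensor(rng.standard_normal((4, d_k)), requires_grad=True)
        if op_id == "standard_scores":
            Q, K = mk(), mk()
            pre = (Q.data @ K.data.T) / math.sqrt(d_k)
            if _has_score_ties(pre[None]):
                warnings.warn("tied pre-softmax scores; re-seeding gradcheck")
                return gradcheck(op_id, seed + 1, eps)
            dev, n = _fd_max_dev(lambda: standard_scores(Q, K, d_k).sum(), [Q, K], eps)
        else:
            Q, K1, K2 = mk(), mk(), mk()
            pre = (Q.data @ K1.data.T + Q.data @ K2.data.T) / math.sqrt(d_k)
            if _has_score_ties(pre[None]):
                warnings.warn("tied pre-softmax scores; re-seeding gradcheck")
                return gradcheck(op_id, seed + 1, eps)
            dev, n = _fd_max_dev(
                lambda: da_scores(Q, K1, K2, d_k).sum(), [Q, K1, K2], eps
            )
        return GradCheckReport(op_id, dev, n, seed=seed)

    if op_id == "attention_forward":
        cfg = AttentionConfig(C=4, M=2, num_heads=2, variant="DA")
        wts = init_attention_weights(cfg, rng, std=0.5)
        x = Tensor(rng.standard_normal((4, 4, cfg.C)), requires_grad=True)
        params = [x] + [t for t in wts.named().values()]

        def loss():
            for t in params:
                t.grad = None
            return attention_forward(x, wts, cfg).sum()

        dev, n = _fd_max_dev(loss, params, eps)

        def wq_grad(block):
            for t in params:
                t.grad = None
            attention_forward(x, wts, cfg, _block_path=block).sum().backward()
            return np.abs(wts.W_Q.grad).max()

        dual = bool(wq_grad("k1") > 0.0) and bool(wq_grad("k2") > 0.0)
        return GradCheckReport(op_id, dev, n, dual_path_ok=dual, seed=seed)

    raise ValueError(
        f"unknown op_id {op_id!r}; expected one of "
        "('linear', 'standard_scores', 'da_scores', 'attention_forward')"
    )
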