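"""Exact complexity accounting: symbolic operation counts and model audits.

Two layers of accounting are provided.

1. The closed-form operation counts of four attention mechanisms over an
   h x w x C feature map (window size M):

       omega_msa  = 4 h w C^2 + 2 (h w)^2 C        (global attention)
       omega_wmsa = 4 h w C^2 + 2 M^2 h w C        (windowed, single Key)
       omega_da   = 5 h w C^2 + 3 M^2 h w C        (windowed, dual Key)
       omega_gaa  = 4 h w C^2 + 2 (h^2 + w^2) C    (gated axial attention)

   These are evaluated in exact (arbitrary-precision) Python integers.

2. Whole-model audits from shapes alone: :func:`count_params` enumerates
   every learnable scalar of a configured backbone without instantiating
   it, and :func:`count_flops` counts multiply-accumulates (MACs) for one
   input under a named convention:

   - ``projections-only``: MACs of every *learned affine* map — patch
     embedding, Q/K1/K2/V and output projections, MLPs, patch-merging
     reductions, the classification head, and the per-element
     scale-and-shift of each normalization layer (gamma*x + beta is one
     MAC per element).  The attention score (Q K^T) and aggregation
     (A V) matrix products, which carry no learned weights, are excluded.
   - ``eq78``: the same count plus the windowed score/aggregation matrix
     products (2 M^2 h w C per single-Key block, 3 M^2 h w C per
     dual-Key block).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .model import ModelConfig

__all__ = [
    "ComplexityQuery",
    "ComplexityReport",
    "omega_msa",
    "omega_wmsa",
    "omega_da",
    "omega_gaa",
    "count_params",
    "count_flops",
    "round_scaled",
    "complexity_report",
    "CONVENTIONS",
]

CONVENTIONS = ("projections-only", "eq78")


@dataclass(frozen=True)
class ComplexityQuery:
    """Spatial extent (tokens), channels and window size for the formulas."""

    h: int
    w: int
    C: int
    M: int = 1

    def __post_init__(self):
        for name in ("h", "w", "C", "M"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


def _ints(q: ComplexityQuery) -> tuple[int, int, int, int]:
    return int(q.h), int(q.w), int(q.C), int(q.M)


def omega_msa(q: ComplexityQuery) -> int:
    """Global multi-head self-attention: 4hwC^2 + 2(hw)^2 C."""
    h, w, C, _ = _ints(q)
    return 4 * h * w * C * C + 2 * (h * w) ** 2 * C


def omega_wmsa(q: ComplexityQuery) -> int:
    """Window attention: 4hwC^2 + 2 M^2 hw C."""
    h, w, C, M = _ints(q)
    return 4 * h * w * C * C + 2 * M * M * h * w * C


def omega_da(q: ComplexityQuery) -> int:
    """Dual-Key window attention: 5hwC^2 + 3 M^2 hw C.

    Exceeds :func:`omega_wmsa` by hwC^2 + M^2 hwC for every query — the
    K2 projection plus the extra Q K2^T product.
    """
    h, w, C, M = _ints(q)
    return 5 * h * w * C * C + 3 * M * M * h * w * C


def omega_gaa(q: ComplexityQuery) -> int:
    """Gated axial attention: 4hwC^2 + 2(h^2 + w^2) C."""
    h, w, C, _ = _ints(q)
    return 4 * h * w * C * C + 2 * (h * h + w * w) * C


# ----------------------------------------------------------------------
# whole-model audits (pure shape arithmetic; exact integers)


def _per_block_params(C: int, H: int, M: int, cfg: ModelConfig) -> int:
    hidden = int(cfg.mlp_ratio * C)
    n = 0
    n += 2 * C  # ln1
    proj_bias = C if cfg.use_bias else 0
    n_proj = 5 if cfg.variant in ("DA", "DA_N") else 4  # Q, K1, (K2), V, out
    n += n_proj * (C * C + proj_bias)
    if cfg.use_relpos:
        n += (2 * M - 1) ** 2 * H
    n += 2 * C  # ln2
    n += C * hidden + hidden + hidden * C + C  # MLP
    return n


def count_params(cfg: ModelConfig) -> int:
    """Exact learnable-scalar count of a configured model, from shapes alone.

    Matches ``build_model(cfg).n_params()`` exactly for every valid
    config (cross-checked in the test suite).
    """
    P, C0 = cfg.patch_size, cfg.embed_dim
    total = P * P * 3 * C0 + C0 + 2 * C0  # embedding + its norm
    for s, depth in enumerate(cfg.depths):
        C, H = cfg.stage_dim(s), cfg.heads[s]
        total += depth * _per_block_params(C, H, cfg.M, cfg)
        if s < cfg.n_stages - 1:
            total += 2 * 4 * C + 4 * C * 2 * C  # merging LN + bias-free reduction
    Cf = cfg.stage_dim(cfg.n_stages - 1)
    total += 2 * Cf  # final norm
    total += Cf * cfg.num_classes + cfg.num_classes  # head
    return total


def count_flops(cfg: ModelConfig, input_hw: tuple[int, int] | None = None,
                convention: str = "projections-only") -> int:
    """Exact MAC count for one forward pass under a named convention."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    hw_in = tuple(input_hw) if input_hw is not None else cfg.input_hw
    P, C0, M = cfg.patch_size, cfg.embed_dim, cfg.M
    h, w = hw_in[0] // P, hw_in[1] // P
    if hw_in[0] % P or hw_in[1] % P:
        raise ValueError(f"input {hw_in} not divisible by patch size {P}")
    total = h * w * C0 * (P * P * 3)  # embedding projection
    total += h * w * C0  # embedding norm affine
    dual = cfg.variant in ("DA", "DA_N")
    for s, depth in enumerate(cfg.depths):
        C = cfg.stage_dim(s)
        hidden = int(cfg.mlp_ratio * C)
        per_block = (5 if dual else 4) * h * w * C * C  # Q,K1,(K2),V,out
        per_block += h * w * (C * hidden + hidden * C)  # MLP
        per_block += 2 * h * w * C  # two norm affines
        if convention == "eq78":
            per_block += (3 if dual else 2) * M * M * h * w * C
        total += depth * per_block
        if s < cfg.n_stages - 1:
            total += (h // 2) * (w // 2) * (4 * C) * (2 * C)  # merging reduction
            total += (h // 2) * (w // 2) * 4 * C  # merging norm affine
            h, w = h // 2, w // 2
    Cf = cfg.stage_dim(cfg.n_stages - 1)
    total += h * w * Cf  # final norm affine
    total += Cf * cfg.num_classes  # head
    return total


def round_scaled(value: int, scale: float = 1e9, decimals: int = 1) -> float:
    """Round an exact count onto the printed scale (G or M), half away
    from zero."""
    x = Fraction(value) / Fraction(int(scale))
    q = Fraction(10) ** decimals
    scaled = x * q
    n = scaled.numerator // scaled.denominator
    rem = scaled - n
    if rem * 2 >= 1:
        n += 1
    return float(Fraction(n) / q)


@dataclass(frozen=True)
class ComplexityReport:
    """Omega values for one query plus exact audits of a configured model."""

    omega_msa: int
    omega_wmsa: int
    omega_da: int
    omega_gaa: int
    params_total: int
    flops_total: int
    convention: str

    @property
    def params_M(self) -> float:
        return round_scaled(self.params_total, 1e6)

    @property
    def flops_G(self) -> float:
        return round_scaled(self.flops_total, 1e9)


def complexity_report(cfg: ModelConfig, input_hw: tuple[int, int] | None = None,
                      convention: str = "projections-only") -> ComplexityReport:
    """Audit a configured model and evaluate the omega formulas at its
    stage-0 token resolution."""
    hw_in = tuple(input_hw) if input_hw is not None else cfg.input_hw
    q = ComplexityQuery(
        h=hw_in[0] // cfg.patch_size, w=hw_in[1] // cfg.patch_size,
        C=cfg.embed_dim, M=cfg.M,
    )
    return ComplexityReport(
        omega_msa=omega_msa(q),
        omega_wmsa=omega_wmsa(q),
        omega_da=omega_da(q),
        omega_gaa=omega_gaa(q),
        params_total=count_params(cfg),
        flops_total=count_flops(cfg, hw_in, convention),
        convention=convention,
    )
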