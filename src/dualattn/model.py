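"""Four-stage window-transformer backbone with dual-Key attention blocks.

The layout follows the hierarchical Swin recipe: a patch-embedding stem,
four stages of pre-norm transformer blocks at resolutions (H/4)/2^s and
channel widths C*2^s, 2x2 patch merging between stages, and a global
average-pool classification head.  Every block uses the configured
attention variant (WMSA / DA_N / DA); there are no alternating
shifted-window blocks — in the DA variant, cross-window information flows
through the K2 pathway of each block instead.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, gelu, layer_norm, softmax
from .attention import (
    AttentionConfig,
    AttentionWeights,
    attention_forward,
    init_attention_weights,
    trunc_normal,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "Model",
    "BlockWeights",
    "TINY",
    "MINI",
    "build_model",
    "patch_embed",
    "patch_merging",
    "transformer_block",
    "classify",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The defaults are the "Tiny" configuration: embed dim 96, depths
    (2, 2, 6, 2), heads (3, 6, 12, 24), window 7, patch 4, 224x224 input.
    """

    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    M: int = 7
    mlp_ratio: float = 4.0
    num_classes: int = 2
    variant: str = "DA"
    input_hw: tuple[int, int] = (224, 224)
    use_relpos: bool = True
    use_bias: bool = True
    dropout: float = 0.0
    drop_path: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "depths", tuple(self.depths))
        object.__setattr__(self, "heads", tuple(self.heads))
        object.__setattr__(self, "input_hw", tuple(self.input_hw))
        errs = []
        if len(self.depths) != len(self.heads):
            errs.append(f"depths {self.depths} and heads {self.heads} differ in length")
        if self.num_classes < 2:
            errs.append(f"num_classes must be >= 2, got {self.num_classes}")
        if self.variant not in ("WMSA", "DA_N", "DA"):
            errs.append(f"unknown variant {self.variant!r}")
        for s, H in enumerate(self.heads):
            C = self.embed_dim * 2**s
            if C % H != 0:
                errs.append(f"stage {s}: channel count {C} not divisible by heads {H}")
        for side in self.input_hw:
            if side % self.patch_size:
                errs.append(f"input side {side} not divisible by patch_size {self.patch_size}")
            else:
                tokens = side // self.patch_size
                for s in range(len(self.depths)):
                    grid = tokens // 2**s
                    if tokens % 2**s or grid % self.M:
                        errs.append(
                            f"stage {s}: token grid {grid} not divisible by window M={self.M}"
                        )
                        break
        if errs:
            raise ValueError("invalid model config: " + "; ".join(errs))

    @property
    def n_stages(self) -> int:
        return len(self.depths)

    def stage_dim(self, s: int) -> int:
        return self.embed_dim * 2**s

    def stage_grid(self, s: int) -> tuple[int, int]:
        return (
            self.input_hw[0] // self.patch_size // 2**s,
            self.input_hw[1] // self.patch_size // 2**s,
        )

    def attn_config(self, s: int) -> AttentionConfig:
        return AttentionConfig(
            C=self.stage_dim(s),
            M=self.M,
            num_heads=self.heads[s],
            variant=self.variant,
            use_bias=self.use_bias,
            use_relpos=self.use_relpos,
        )


TINY = ModelConfig()
#: a desk-scale two-stage model for synthetic experiments (56x56 input)
MINI = ModelConfig(
    embed_dim=32, depths=(1, 1), heads=(2, 4), input_hw=(56, 56), num_classes=2
)


@dataclass
class BlockWeights:
    """One transformer block: pre-norm attention + pre-norm MLP."""

    ln1_g: Tensor
    ln1_b: Tensor
    attn: AttentionWeights
    ln2_g: Tensor
    ln2_b: Tensor
    mlp_W1: Tensor
    mlp_b1: Tensor
    mlp_W2: Tensor
    mlp_b2: Tensor

    def named(self) -> dict:
        out = {f"attn.{k}": v for k, v in self.attn.named().items()}
        for k in ("ln1_g", "ln1_b", "ln2_g", "ln2_b", "mlp_W1", "mlp_b1", "mlp_W2", "mlp_b2"):
            out[k] = getattr(self, k)
        return out


# ----------------------------------------------------------------------
# layer ops


def patch_embed(images, W, b, ln_g, ln_b, patch_size: int):
    """Embed non-overlapping P x P patches with a learned linear map + LN.

    ``images`` is (..., H, W, 3) in any numeric range; grayscale input
    (trailing channel 1, or no channel axis) is replicated to 3 channels
    with a warning.  Output is (..., H/P, W/P, C).
    """
    tensor_in = isinstance(images, Tensor)
    x = images if tensor_in else Tensor(np.asarray(images, dtype=np.float64))
    if x.ndim >= 1 and x.shape[-1] not in (1, 3):
        # no channel axis at all: treat as grayscale plane
        if x.ndim >= 2 and x.shape[-1] == x.shape[-2]:
            x = x.reshape(x.shape + (1,))
        else:
            raise ValueError(f"expected 1 or 3 channels, got shape {x.shape}")
    if x.shape[-1] == 1:
        warnings.warn("grayscale input replicated to 3 channels")
        data = np.repeat(x.data, 3, axis=-1)
        x = Tensor(data, requires_grad=x.requires_grad) if tensor_in else Tensor(data)
    P = patch_size
    h, w = x.shape[-3], x.shape[-2]
    if h % P or w % P:
        pad_h, pad_w = (-h) % P, (-w) % P
        logger.info("patch_embed: reflect-padding input by (%d, %d)", pad_h, pad_w)
        data = np.pad(
            x.data,
            [(0, 0)] * (x.ndim - 3) + [(0, pad_h), (0, pad_w), (0, 0)],
            mode="reflect",
        )
        x = Tensor(data)
        h, w = h + pad_h, w + pad_w
    lead = x.shape[:-3]
    x = x.reshape(lead + (h // P, P, w // P, P, 3))
    ax = len(lead)
    x = x.transpose(tuple(range(ax)) + (ax, ax + 2, ax + 1, ax + 3, ax + 4))
    x = x.reshape(lead + (h // P, w // P, P * P * 3))
    out = x @ W + b
    out = layer_norm(out, ln_g, ln_b)
    return out if tensor_in else out.data


def patch_merging(fm, ln_g, ln_b, W_red):
    """Concatenate each 2x2 token neighborhood (4C), normalize, project to 2C."""
    tensor_in = isinstance(fm, Tensor)
    x = fm if tensor_in else Tensor(np.asarray(fm))
    h, w, C = x.shape[-3], x.shape[-2], x.shape[-1]
    if h % 2 or w % 2:
        raise ValueError(f"patch merging requires even sides, got {h}x{w}")
    lead = x.shape[:-3]
    x = x.reshape(lead + (h // 2, 2, w // 2, 2, C))
    ax = len(lead)
    x = x.transpose(tuple(range(ax)) + (ax, ax + 2, ax + 1, ax + 3, ax + 4))
    x = x.reshape(lead + (h // 2, w // 2, 4 * C))
    x = layer_norm(x, ln_g, ln_b)
    out = x @ W_red
    return out if tensor_in else out.data


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask


def transformer_block(
    fm,
    bw: BlockWeights,
    acfg: AttentionConfig,
    mlp_ratio: float = 4.0,
    *,
    dropout: float = 0.0,
    drop_path: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Pre-norm block: y = x + Attn(LN(x)); out = y + MLP(LN(y)).

    The MLP is linear C -> mlp_ratio*C, GELU, linear back.  ``dropout``
    and ``drop_path`` are active only when an ``rng`` is supplied
    (training mode).
    """
    tensor_in = isinstance(fm, Tensor)
    x = fm if tensor_in else Tensor(np.asarray(fm))

    def maybe_drop_path(branch: Tensor) -> Tensor:
        if drop_path <= 0.0 or rng is None:
            return branch
        keep = (rng.random() >= drop_path) / (1.0 - drop_path)
        return branch * keep

    a = attention_forward(layer_norm(x, bw.ln1_g, bw.ln1_b), bw.attn, acfg)
    a = _dropout(a, dropout, rng)
    y = x + maybe_drop_path(a)
    hmid = gelu(layer_norm(y, bw.ln2_g, bw.ln2_b) @ bw.mlp_W1 + bw.mlp_b1)
    hmid = _dropout(hmid, dropout, rng)
    m = hmid @ bw.mlp_W2 + bw.mlp_b2
    m = _dropout(m, dropout, rng)
    out = y + maybe_drop_path(m)
    return out if tensor_in else out.data


# ----------------------------------------------------------------------
# the model


class Model:
    """A built backbone: config plus named parameter Tensors."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.embed: dict[str, Tensor] = {}
        self.stages: list[list[BlockWeights]] = []
        self.mergings: list[dict[str, Tensor]] = []
        self.final: dict[str, Tensor] = {}

    # -- parameter bookkeeping -----------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out = {f"embed.{k}": v for k, v in self.embed.items()}
        for s, blocks in enumerate(self.stages):
            for b, bw in enumerate(blocks):
                for k, v in bw.named().items():
                    out[f"stage{s}.block{b}.{k}"] = v
            if s < len(self.mergings):
                for k, v in self.mergings[s].items():
                    out[f"merge{s}.{k}"] = v
        for k, v in self.final.items():
            out[f"final.{k}"] = v
        return out

    def n_params(self) -> int:
        return sum(int(t.data.size) for t in self.parameters().values())

    def zero_grad(self) -> None:
        for t in self.parameters().values():
            t.grad = None

    # -- forward --------------------------------------------------------
    def forward(self, images, *, training: bool = False, rng=None) -> Tensor:
        """Map (N, H, W, 3) images to (N, num_classes) logits."""
        cfg = self.config
        x = patch_embed(
            Tensor(np.asarray(images, dtype=np.float64)),
            self.embed["W"], self.embed["b"], self.embed["ln_g"], self.embed["ln_b"],
            cfg.patch_size,
        )
        use_rng = rng if training else None
        for s, blocks in enumerate(self.stages):
            acfg = cfg.attn_config(s)
            for bw in blocks:
                x = transformer_block(
                    x, bw, acfg, cfg.mlp_ratio,
                    dropout=cfg.dropout, drop_path=cfg.drop_path, rng=use_rng,
                )
            if s < len(self.mergings):
                mg = self.mergings[s]
                x = patch_merging(x, mg["ln_g"], mg["ln_b"], mg["W_red"])
        x = layer_norm(x, self.final["ln_g"], self.final["ln_b"])
        # global average pool over the token grid
        x = x.reshape(x.shape[:-3] + (x.shape[-3] * x.shape[-2], x.shape[-1]))
        x = x.mean(axis=-2)
        return x @ self.final["head_W"] + self.final["head_b"]

    def logits(self, images) -> np.ndarray:
        return self.forward(images).data


def build_model(cfg: ModelConfig, seed: int = 0) -> Model:
    """Deterministically construct and initialize a model from its config.

    Projections are truncated-normal (sigma 0.02), biases and the
    relative-position tables start at zero-mean; normalization scales
    start at one.  The same seed always yields bit-identical weights.
    """
    rng = np.random.default_rng(seed)
    m = Model(cfg)
    C0 = cfg.embed_dim

    def param(shape, init="tn"):
        if init == "tn":
            return Tensor(trunc_normal(rng, shape), requires_grad=True)
        if init == "zeros":
            return Tensor(np.zeros(shape), requires_grad=True)
        if init == "ones":
            return Tensor(np.ones(shape), requires_grad=True)
        raise AssertionError(init)

    P = cfg.patch_size
    m.embed = {
        "W": param((P * P * 3, C0)),
        "b": param((C0,), "zeros"),
        "ln_g": param((C0,), "ones"),
        "ln_b": param((C0,), "zeros"),
    }
    for s, depth in enumerate(cfg.depths):
        C = cfg.stage_dim(s)
        hidden = int(cfg.mlp_ratio * C)
        blocks = []
        for _ in range(depth):
            blocks.append(
                BlockWeights(
                    ln1_g=param((C,), "ones"),
                    ln1_b=param((C,), "zeros"),
                    attn=init_attention_weights(cfg.attn_config(s), rng),
                    ln2_g=param((C,), "ones"),
                    ln2_b=param((C,), "zeros"),
                    mlp_W1=param((C, hidden)),
                    mlp_b1=param((hidden,), "zeros"),
                    mlp_W2=param((hidden, C)),
                    mlp_b2=param((C,), "zeros"),
                )
            )
        m.stages.append(blocks)
        if s < cfg.n_stages - 1:
            m.mergings.append(
                {
                    "ln_g": param((4 * C,), "ones"),
                    "ln_b": param((4 * C,), "zeros"),
                    "W_red": param((4 * C, 2 * C)),
                }
            )
    Cf = cfg.stage_dim(cfg.n_stages - 1)
    m.final = {
        "ln_g": param((Cf,), "ones"),
        "ln_b": param((Cf,), "zeros"),
        "head_W": param((Cf, cfg.num_classes)),
        "head_b": param((cfg.num_classes,), "zeros"),
    }
    return m


def classify(model: Model, images) -> np.ndarray:
    """Per-class probabilities for a batch of images; rows sum to 1."""
    images = np.asarray(images, dtype=np.float64)
    if images.size == 0:
        return np.zeros((0, model.config.num_classes))
    return softmax(model.forward(images), axis=-1).data


# ----------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: Model, path) -> None:
    """Write a flat named-array checkpoint (.npz) plus the config record."""
    arrays = {k: v.data for k, v in model.parameters().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(model: Model, path) -> list[str]:
    """Load matching entries into ``model``; skip and log every mismatch.

    Entries whose name is absent from the current model, or whose shape
    disagrees, are skipped (mirroring initialization from a pretrained
    file with a different attention parameterization).  Returns the list
    of skipped names.
    """
    data = np.load(path)
    params = model.parameters()
    skipped = []
    for name in data.files:
        if name == "__config__":
            continue
        if name not in params or params[name].data.shape != data[name].shape:
            skipped.append(name)
            logger.warning("checkpoint entry skipped: %s", name)
            continue
        params[name].data = data[name].astype(np.float64)
    for name in params:
        if name not in data.files:
            skipped.append(f"(missing) {name}")
            logger.warning("model parameter not in checkpoint: %s", name)
    return skipped
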