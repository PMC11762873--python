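"""Desk-scale supervised training with best-on-validation selection.

The protocol mirrors the standard fine-tuning loop: cross-entropy loss,
per-epoch train/validation accuracy curves, and retention of the
checkpoint with the best validation accuracy (ties broken by the
earliest epoch); test accuracy is then reported on that checkpoint.

Two optimizers are provided.  ``sgd`` is the literal per-parameter
update  theta(t+1) = theta(t) - eta * dL/dtheta,  the form under which
the dual gradient path of the summed attention score acts; ``adamw``
(decoupled weight decay, optional cosine schedule with warmup) is the
configurable default for actually fitting models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import cross_entropy
from .model import Model, ModelConfig, build_model
from .synth import DatasetSplit, LabeledImageSet, augment_batch

__all__ = [
    "TrainConfig",
    "TrainState",
    "History",
    "TrainingDiverged",
    "train",
    "evaluate",
    "select_best_epoch",
    "compare_variants",
    "build_variant_family",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; ``eta`` is the learning rate."""

    eta: float = 1e-3
    optimizer: str = "adamw"
    epochs: int = 20
    batch_size: int = 12
    weight_decay: float = 0.0
    seed: int = 0
    augment: bool = False
    schedule: str = "constant"  # or "cosine"
    warmup_epochs: int = 0
    #: stop once the epoch train accuracy reaches this level (None: never)
    early_stop_train_acc: float | None = None

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer not in ("sgd", "adamw"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass
class TrainState:
    """Progress of one run: step counter, current loss, best-so-far."""

    t: int = 0
    L: float = float("nan")
    best_val_acc: float = -1.0
    best_checkpoint_id: int = -1  # epoch index of the retained checkpoint


@dataclass
class History:
    """Per-epoch curves; list lengths equal the number of completed epochs."""

    train_acc: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    loss: list = field(default_factory=list)

    def rows(self):
        for e, (ta, va, lo) in enumerate(zip(self.train_acc, self.val_acc, self.loss)):
            yield e, ta, va, lo

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_acc,val_acc,loss\n")
            for e, ta, va, lo in self.rows():
                fh.write(f"{e},{ta:.6f},{va:.6f},{lo:.6f}\n")


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int, step: int):
        super().__init__(f"non-finite loss at epoch {epoch}, step {step}")
        self.epoch, self.step = epoch, step


def _lr_at(tc: TrainConfig, epoch: int) -> float:
    if tc.schedule == "constant":
        return tc.eta
    if epoch < tc.warmup_epochs:
        return tc.eta * (epoch + 1) / max(1, tc.warmup_epochs)
    span = max(1, tc.epochs - tc.warmup_epochs)
    frac = (epoch - tc.warmup_epochs) / span
    return tc.eta * 0.5 * (1.0 + math.cos(math.pi * frac))


class _AdamW:
    def __init__(self, params: dict, wd: float):
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0
        self.wd = wd
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict, lr: float) -> None:
        self.t += 1
        for k, p in params.items():
            g = p.grad if p.grad is not None else 0.0
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


def _sgd_step(params: dict, lr: float, wd: float) -> None:
    # the literal update theta <- theta - eta * grad (plus optional decay)
    for p in params.values():
        if p.grad is not None:
            p.data -= lr * p.grad
        if wd:
            p.data -= lr * wd * p.data


def _accuracy_from_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    return float((logits.argmax(axis=-1) == labels).mean())


def evaluate(model: Model, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 32) -> float:
    """Fraction of argmax-correct predictions; order-invariant."""
    if len(labels) == 0:
        raise ValueError("cannot evaluate on an empty split")
    correct = 0
    for i in range(0, len(labels), batch_size):
        logits = model.logits(images[i : i + batch_size])
        correct += int((logits.argmax(axis=-1) == labels[i : i + batch_size]).sum())
    return correct / len(labels)


def select_best_epoch(val_accs) -> int:
    """Argmax of validation accuracy; ties broken by the earliest epoch."""
    if len(val_accs) == 0:
        raise ValueError("empty history")
    arr = np.asarray(val_accs, dtype=np.float64)
    return int(np.argmax(arr))  # np.argmax returns the first maximum


def _snapshot(model: Model) -> dict:
    return {k: t.data.copy() for k, t in model.parameters().items()}


def _restore(model: Model, snap: dict) -> None:
    for k, t in model.parameters().items():
        t.data = snap[k].copy()


def train(
    model: Model,
    data: LabeledImageSet,
    splits: DatasetSplit,
    tc: TrainConfig,
) -> tuple[History, dict, TrainState]:
    """Fit ``model`` on the train split, track curves, and keep the
    checkpoint with the best validation accuracy.

    Returns (history, best_parameter_snapshot, final_state).  With
    ``epochs = 0`` the history is empty and the snapshot is the initial
    weights.  A non-finite loss aborts with the epoch and step recorded
    on the raised :class:`TrainingDiverged`.
    """
    if tc.epochs > 0 and (len(splits.train) == 0 or len(splits.val) == 0):
        raise ValueError("train and val splits must be non-empty")
    rng = np.random.default_rng(tc.seed)
    params = model.parameters()
    opt = _AdamW(params, tc.weight_decay) if tc.optimizer == "adamw" else None
    hist = History()
    state = TrainState()
    best = _snapshot(model)
    state.best_checkpoint_id = -1

    X, y = data.images, data.labels
    for epoch in range(tc.epochs):
        lr = _lr_at(tc, epoch)
        order = rng.permutation(splits.train)
        epoch_losses, epoch_correct, epoch_total = [], 0, 0
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb, yb = X[idx], y[idx]
            if tc.augment:
                xb = augment_batch(xb, rng)
            model.zero_grad()
            logits = model.forward(xb, training=True, rng=rng)
            loss = cross_entropy(logits, yb)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise TrainingDiverged(epoch, state.t)
            loss.backward()
            if opt is not None:
                opt.step(params, lr)
            else:
                _sgd_step(params, lr, tc.weight_decay)
            state.t += 1
            state.L = lval
            epoch_losses.append(lval)
            epoch_correct += int((logits.data.argmax(-1) == yb).sum())
            epoch_total += len(yb)
        hist.train_acc.append(epoch_correct / max(1, epoch_total))
        hist.val_acc.append(evaluate(model, X[splits.val], y[splits.val]))
        hist.loss.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        if hist.val_acc[-1] > state.best_val_acc:  # strict: earliest tie wins
            state.best_val_acc = hist.val_acc[-1]
            state.best_checkpoint_id = epoch
            best = _snapshot(model)
        if (
            tc.early_stop_train_acc is not None
            and hist.train_acc[-1] >= tc.early_stop_train_acc
        ):
            break
    return hist, best, state


# ----------------------------------------------------------------------
# variant comparison


def build_variant_family(base_cfg: ModelConfig, seed: int = 0) -> dict[str, Model]:
    """Build WMSA / DA_N / DA models whose shared (non-K2) parameters are
    bit-identical at initialization.

    The DA model is built first; every parameter it shares with the
    other variants is copied over, so the only differences are the K2
    projections (absent for WMSA, identically initialized for DA_N).
    """
    from dataclasses import replace

    ref = build_model(replace(base_cfg, variant="DA"), seed)
    ref_params = {k: t.data for k, t in ref.parameters().items()}
    family: dict[str, Model] = {}
    for variant in ("WMSA", "DA_N", "DA"):
        if variant == "DA":
            family[variant] = ref
            continue
        m = build_model(replace(base_cfg, variant=variant), seed)
        for k, t in m.parameters().items():
            if k in ref_params and ref_params[k].shape == t.data.shape:
                t.data = ref_params[k].copy()
        family[variant] = m
    return family


def compare_variants(
    data: LabeledImageSet,
    base_cfg: ModelConfig,
    tc: TrainConfig,
    seeds=(0, 1, 2),
    variants=("WMSA", "DA_N", "DA"),
) -> dict:
    """Train each attention variant under identical budgets and seeds.

    For every seed the data split, the batch order, and all shared
    initial weights are identical across variants.  Returns a report
    mapping variant -> {"val_accs", "test_accs", "mean_val_acc",
    "mean_test_acc", "params", "histories"}.
    """
    from dataclasses import replace

    from .complexity import count_flops, count_params, round_scaled
    from .synth import split_622

    report: dict = {}
    for variant in variants:
        cfg = replace(base_cfg, variant=variant)
        report[variant] = {
            "val_accs": [],
            "test_accs": [],
            "histories": [],
            "params_total": count_params(cfg),
            "params_M": round_scaled(count_params(cfg), 1e6),
            "flops_total": count_flops(cfg),
            "flops_G": round_scaled(count_flops(cfg), 1e9),
        }
    for seed in seeds:
        splits = split_622(len(data), seed=seed)
        family = build_variant_family(base_cfg, seed=seed)
        for variant in variants:
            model = family[variant]
            tc_seed = replace(tc, seed=seed)
            hist, best, state = train(model, data, splits, tc_seed)
            _restore(model, best)
            test_acc = evaluate(model, data.images[splits.test], data.labels[splits.test])
            rep = report[variant]
            if state.best_checkpoint_id < 0:  # zero-epoch budget: score the init
                state.best_val_acc = evaluate(
                    model, data.images[splits.val], data.labels[splits.val]
                )
            rep["val_accs"].append(state.best_val_acc)
            rep["test_accs"].append(test_acc)
            rep["histories"].append(hist)
    for variant in variants:
        rep = report[variant]
        rep["mean_val_acc"] = float(np.mean(rep["val_accs"]))
        rep["mean_test_acc"] = float(np.mean(rep["test_accs"]))
    return report
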