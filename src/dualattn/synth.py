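"""Synthetic labeled-image tasks exercising cross-window dependencies.

The ``cross_window`` task is the heart of the harness: every image
carries one oriented motif in each of two horizontally adjacent attention
windows, and the class is determined solely by whether the two
orientations *match*.  Each window viewed alone contains a motif of
uniformly random orientation whatever the class, so no within-window
statistic separates the classes — a classifier must combine information
across the window boundary, which is exactly the pathway the dual-Key
attention adds.  The ``blob`` task is a linearly separable smoke test
(class encoded in the mean intensity of one centered blob).

Images are float arrays in [0, 1]; generation is integer-lattice
stamping plus seeded Gaussian noise, so datasets are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticTaskSpec",
    "LabeledImageSet",
    "DatasetSplit",
    "generate",
    "gen_cross_window",
    "gen_blob",
    "split_622",
    "augment_batch",
    "write_imagefolder",
    "load_imagefolder",
]


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Parameters of a generated classification dataset.

    ``window_px`` is the attention window size in pixels (window size in
    tokens times the patch size; 7 * 4 = 28 by default), and the motif
    must fit inside one window.
    """

    n_samples: int
    image_hw: tuple[int, int] = (56, 56)
    n_classes: int = 2
    motif_size: int = 5
    noise_sd: float = 0.0
    task: str = "cross_window"
    seed: int = 0
    window_px: int = 28

    def __post_init__(self):
        object.__setattr__(self, "image_hw", tuple(self.image_hw))
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.task not in ("cross_window", "blob"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.motif_size > self.window_px:
            raise ValueError(
                f"motif_size {self.motif_size} exceeds window_px {self.window_px}"
            )
        if self.task == "cross_window" and (
            self.image_hw[0] < self.window_px or self.image_hw[1] < 2 * self.window_px
        ):
            raise ValueError(
                f"image {self.image_hw} too small for two adjacent "
                f"{self.window_px}-px windows"
            )


@dataclass
class LabeledImageSet:
    """Images (n, h, w, 3) in [0, 1] with integer labels."""

    images: np.ndarray
    labels: np.ndarray
    spec: SyntheticTaskSpec
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train/val/test index lists at a 6:2:2 ratio."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)


def _balanced_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly floor(n/2) of class 1, the rest class 0, shuffled."""
    labels = np.zeros(n, dtype=np.int64)
    labels[: n // 2] = 1
    rng.shuffle(labels)
    return labels


def _motif(size: int, orientation: int) -> np.ndarray:
    """A size x size x 3 oriented stamp.

    Orientation 0 is the main diagonal drawn in the red channel,
    orientation 1 the anti-diagonal drawn in the blue channel.  Encoding
    the binary attribute in both shape and channel keeps it readable
    after the global average pooling of small backbones, where a purely
    geometric cue would wash out.
    """
    m = np.zeros((size, size, 3), dtype=np.float64)
    diag = np.eye(size, dtype=np.float64)
    if orientation == 0:
        m[:, :, 0] = diag
    else:
        m[:, :, 2] = diag[:, ::-1]
    return m


def gen_cross_window(spec: SyntheticTaskSpec) -> LabeledImageSet:
    """Two oriented motifs in horizontally adjacent windows; class 1 iff
    the orientations match.

    Motif positions are uniform within each window; labels are balanced
    to within one sample and the orientation seen in either single
    window is uniform regardless of class.
    """
    if spec.task != "cross_window":
        raise ValueError("spec.task must be 'cross_window'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    h, w = spec.image_hw
    wp, ms = spec.window_px, spec.motif_size
    labels = _balanced_labels(n, rng)
    images = np.zeros((n, h, w, 3), dtype=np.float64)
    orientations = np.zeros((n, 2), dtype=np.int64)
    for i in range(n):
        o1 = int(rng.integers(2))
        o2 = o1 if labels[i] == 1 else 1 - o1
        orientations[i] = (o1, o2)
        for widx, o in ((0, o1), (1, o2)):
            r0 = int(rng.integers(wp - ms + 1))
            c0 = widx * wp + int(rng.integers(wp - ms + 1))
            images[i, r0 : r0 + ms, c0 : c0 + ms, :] += _motif(ms, o)
    if spec.noise_sd > 0:
        images += rng.normal(0.0, spec.noise_sd, size=images.shape)
    np.clip(images, 0.0, 1.0, out=images)
    return LabeledImageSet(images, labels, spec, meta={"orientations": orientations})


def gen_blob(spec: SyntheticTaskSpec) -> LabeledImageSet:
    """A centered blob whose amplitude encodes the class (separable task)."""
    if spec.task != "blob":
        raise ValueError("spec.task must be 'blob'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    h, w = spec.image_hw
    labels = _balanced_labels(n, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2) / (min(h, w) / 4) ** 2
    bump = np.exp(-r2)
    images = np.zeros((n, h, w, 3), dtype=np.float64)
    amps = np.where(
        labels == 1,
        rng.uniform(0.65, 0.95, size=n),
        rng.uniform(0.05, 0.35, size=n),
    )
    images += amps[:, None, None, None] * bump[None, :, :, None]
    if spec.noise_sd > 0:
        images += rng.normal(0.0, spec.noise_sd, size=images.shape)
    np.clip(images, 0.0, 1.0, out=images)
    return LabeledImageSet(images, labels, spec, meta={"amplitudes": amps})


def generate(spec: SyntheticTaskSpec) -> LabeledImageSet:
    return gen_cross_window(spec) if spec.task == "cross_window" else gen_blob(spec)


def split_622(n_items: int, seed: int = 0) -> DatasetSplit:
    """Seeded shuffle, then train = floor(0.6 n), val = floor(0.2 n),
    test = the remainder; parts are disjoint and exhaustive."""
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    idx = np.random.default_rng(seed).permutation(n_items)
    n_train = int(0.6 * n_items)
    n_val = int(0.2 * n_items)
    return DatasetSplit(
        train=idx[:n_train],
        val=idx[n_train : n_train + n_val],
        test=idx[n_train + n_val :],
    )


def augment_batch(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation: with probability 1/2 each, a random
    90-degree-multiple rotation, a horizontal flip, and a vertical flip."""
    out = images.copy()
    for i in range(len(out)):
        if rng.random() < 0.5:
            out[i] = np.rot90(out[i], k=int(rng.integers(1, 4)), axes=(0, 1))
        if rng.random() < 0.5:
            out[i] = out[i][:, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i][::-1, :]
    return out


# ----------------------------------------------------------------------
# image-folder round trip (one directory per class + manifest CSV)


def write_imagefolder(
    ds: LabeledImageSet, out_dir, split: DatasetSplit | None = None
) -> Path:
    """Write PNGs under ``out_dir/class_<k>/`` plus ``manifest.csv`` with
    columns filename,label,split."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    split_of = {}
    if split is not None:
        for name, idxs in (("train", split.train), ("val", split.val), ("test", split.test)):
            for i in idxs:
                split_of[int(i)] = name
    rows = []
    for i, (img, lab) in enumerate(zip(ds.images, ds.labels)):
        cls_dir = out / f"class_{int(lab)}"
        cls_dir.mkdir(exist_ok=True)
        fname = f"class_{int(lab)}/img_{i:05d}.png"
        arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out / fname)
        rows.append((fname, int(lab), split_of.get(i, "")))
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "split"])
        writer.writerows(rows)
    return out


def load_imagefolder(root, image_hw: tuple[int, int] | None = None):
    """Read a one-directory-per-class folder back into arrays.

    Classes are directory names sorted lexicographically; images are
    bilinearly resized to ``image_hw`` when given.  Returns
    (images, labels, class_names).
    """
    from PIL import Image

    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class directories under {root}")
    images, labels = [], []
    for k, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            im = Image.open(f).convert("RGB")
            if image_hw is not None:
                im = im.resize((image_hw[1], image_hw[0]), Image.BILINEAR)
            images.append(np.asarray(im, dtype=np.float64) / 255.0)
            labels.append(k)
    return np.stack(images), np.asarray(labels, dtype=np.int64), [d.name for d in class_dirs]
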