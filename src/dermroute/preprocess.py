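"""Dataset preparation: stratified splitting, offline augmentation to
target class counts, gray-world color constancy and bicubic resizing.

The reference dataset is ISIC 2018 task 3 restricted to the three
pigmented-lesion classes: benign keratosis (1099), melanoma (1113) and
nevus (6705) — 8917 lesions.  Images are split 70/10/20 into train /
validation / test per class, the training set is augmented offline
(horizontal flip, vertical flip, rotation, width/height shift) up to a
fixed per-class target, and every image is color-corrected and resized
to a square network input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from PIL import Image

from .routing import CLASSES

__all__ = [
    "ISIC2018_CLASS_COUNTS",
    "AUGMENT_TARGETS",
    "SplitFractions",
    "LabeledImageSet",
    "split_counts",
    "split_dataset",
    "augment_to_target",
    "gray_world",
    "resize_input",
    "read_isic_csv",
    "write_isic_csv",
]

#: Lesion counts of the three-class ISIC 2018 task-3 subset.
ISIC2018_CLASS_COUNTS: dict[str, int] = {"B": 1099, "M": 1113, "N": 6705}

#: Offline-augmentation targets for the training split.
AUGMENT_TARGETS: dict[str, int] = {"B": 2000, "M": 2000, "N": 5000}

#: CSV one-hot column name per class label (ISIC 2018 dialect).
ISIC_COLUMNS: dict[str, str] = {"B": "BKL", "M": "MEL", "N": "NV"}
_COLUMN_TO_CLASS = {v: k for k, v in ISIC_COLUMNS.items()}


@dataclass(frozen=True)
class SplitFractions:
    """Train/validation/test fractions; must sum to 1."""

    train: float = 0.7
    val: float = 0.1
    test: float = 0.2

    def __post_init__(self) -> None:
        total = self.train + self.val + self.test
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total})")
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("fractions must be non-negative")


@dataclass
class LabeledImageSet:
    """Images with class labels and optional split membership."""

    items: list  # list of (image_id, image-or-path, class label)
    split: Optional[dict[str, str]] = None  # image_id -> train|val|test

    def __post_init__(self) -> None:
        ids = [i for i, _, _ in self.items]
        if len(ids) != len(set(ids)):
            raise ValueError("image_ids must be unique")
        if self.split is not None and set(self.split) != set(ids):
            raise ValueError("split must cover every item exactly once")

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for _, _, lbl in self.items:
            counts[lbl] += 1
        return counts

    def subset(self, split_name: str) -> "LabeledImageSet":
        if self.split is None:
            raise ValueError("no split assigned")
        kept = [it for it in self.items if self.split[it[0]] == split_name]
        return LabeledImageSet(kept)


def split_counts(n: int, fractions: SplitFractions = SplitFractions()) -> tuple[int, int, int]:
    """(train, val, test) counts for one class of size ``n``.

    Test and validation sizes are rounded half-to-even (banker's
    rounding) and the training set takes the remainder — e.g. 6705
    nevi give a validation size of round(670.5) = 670.
    """
    if n <= 0:
        raise ValueError("class count must be positive")
    # snap to 9 decimals first so binary float noise (0.1*6705 =
    # 670.5000000000001) cannot defeat the half-to-even rule
    n_test = round(round(fractions.test * n, 9))
    n_val = round(round(fractions.val * n, 9))
    n_train = n - n_test - n_val
    if n_train <= 0:
        raise ValueError(f"split of {n} leaves no training samples")
    return n_train, n_val, n_test


def split_dataset(
    data: LabeledImageSet,
    fractions: SplitFractions = SplitFractions(),
    seed: int = 0,
) -> LabeledImageSet:
    """Stratified random 70/10/20 split, deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for c in CLASSES:
        ids = [i for i, _, lbl in data.items if lbl == c]
        if not ids:
            continue
        n_train, n_val, n_test = split_counts(len(ids), fractions)
        perm = rng.permutation(len(ids))
        for pos, idx in enumerate(perm):
            if pos < n_train:
                assignment[ids[idx]] = "train"
            elif pos < n_train + n_val:
                assignment[ids[idx]] = "val"
            else:
                assignment[ids[idx]] = "test"
    return LabeledImageSet(list(data.items), assignment)


# ---------------------------------------------------------------------------
# Offline augmentation
# ---------------------------------------------------------------------------

#: Default augmentation magnitudes (the four transforms are fixed;
#: magnitudes are configurable).
ROTATION_RANGE_DEG = 90.0
SHIFT_RANGE_FRAC = 0.10


def _augment_one(img: np.ndarray, rng: np.random.Generator,
                 rotation_range: float = ROTATION_RANGE_DEG,
                 shift_range: float = SHIFT_RANGE_FRAC) -> np.ndarray:
    """Random composition of horizontal flip, vertical flip, rotation and
    width/height shift applied to one HxWx3 uint8 image."""
    pil = Image.fromarray(np.asarray(img, dtype=np.uint8))
    if rng.random() < 0.5:
        pil = pil.transpose(Image.FLIP_LEFT_RIGHT)
    if rng.random() < 0.5:
        pil = pil.transpose(Image.FLIP_TOP_BOTTOM)
    angle = float(rng.uniform(-rotation_range, rotation_range))
    pil = pil.rotate(angle, resample=Image.BICUBIC)
    dx = float(rng.uniform(-shift_range, shift_range)) * pil.width
    dy = float(rng.uniform(-shift_range, shift_range)) * pil.height
    pil = pil.transform(
        pil.size, Image.AFFINE, (1, 0, dx, 0, 1, dy), resample=Image.BICUBIC
    )
    return np.asarray(pil)


def augment_to_target(
    items: Sequence[tuple],
    target: int,
    seed: int = 0,
    rotation_range: float = ROTATION_RANGE_DEG,
    shift_range: float = SHIFT_RANGE_FRAC,
) -> list[tuple]:
    """Grow one class's training items to exactly ``target`` images.

    Generates ``target - len(items)`` new images by transforming randomly
    chosen originals; originals are retained.  New ids get an ``_augN``
    suffix.  Deterministic given ``seed``.
    """
    if target < len(items):
        raise ValueError(
            f"target {target} below current count {len(items)}"
        )
    rng = np.random.default_rng(seed)
    out = list(items)
    for k in range(target - len(items)):
        image_id, img, lbl = items[rng.integers(len(items))]
        new = _augment_one(img, rng, rotation_range, shift_range)
        out.append((f"{image_id}_aug{k}", new, lbl))
    return out


# ---------------------------------------------------------------------------
# Image normalisation
# ---------------------------------------------------------------------------

def gray_world(image: np.ndarray) -> np.ndarray:
    """Gray-world color constancy: scale each channel so all channel
    means equal the global mean, removing illumination color cast.

    Accepts HxWx3 uint8 or float; returns the same dtype, clipped to the
    valid range.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("gray_world expects an HxWx3 RGB image")
    fl = arr.astype(np.float64)
    means = fl.mean(axis=(0, 1))
    if np.any(means == 0):
        raise ValueError("gray_world: channel with zero mean")
    gains = means.mean() / means
    out = fl * gains[None, None, :]
    if np.issubdtype(arr.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(arr.dtype)
    return np.clip(out, 0.0, 1.0) if fl.max() <= 1.0 else out


def resize_input(image: np.ndarray, size: int = 456) -> np.ndarray:
    """Stretch an image to size x size with bicubic interpolation."""
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.shape[:2] == (size, size):
        return arr.copy()
    pil = Image.fromarray(arr.astype(np.uint8) if arr.dtype != np.uint8 else arr)
    return np.asarray(pil.resize((size, size), Image.BICUBIC))


# ---------------------------------------------------------------------------
# ISIC-dialect ground-truth CSV
# ---------------------------------------------------------------------------

def preprocess_image(
    image: np.ndarray, size: int, color_correct: bool = True
) -> np.ndarray:
    """Standard input normalisation: gray-world, bicubic resize to
    size x size, then scale to float32 in [-0.5, 0.5]."""
    img = gray_world(image) if color_correct else np.asarray(image)
    img = resize_input(img, size)
    return img.astype(np.float32) / 255.0 - 0.5


def to_tensor(
    data: LabeledImageSet, size: Optional[int] = None, color_correct: bool = True
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack a LabeledImageSet into (N, C, H, W) network input plus labels."""
    size = size or np.asarray(data.items[0][1]).shape[0]
    imgs, labels, ids = [], [], []
    for image_id, img, lbl in data.items:
        imgs.append(preprocess_image(img, size, color_correct).transpose(2, 0, 1))
        labels.append(lbl)
        ids.append(image_id)
    return np.stack(imgs), np.asarray(labels), ids


def read_isic_csv(path: Path) -> list[tuple[str, str]]:
    """Read (image_id, class label) pairs from an ISIC 2018 style CSV
    (header: image, then one-hot columns such as MEL, NV, BKL)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = [c for c in reader.fieldnames or [] if c in _COLUMN_TO_CLASS]
        if not cols:
            raise ValueError(f"{path}: no recognised class columns")
        for rec in reader:
            hot = [c for c in cols if float(rec[c]) == 1.0]
            if len(hot) != 1:
                raise ValueError(
                    f"{path}: row {rec.get('image')!r} is not one-hot"
                )
            rows.append((rec["image"], _COLUMN_TO_CLASS[hot[0]]))
    return rows


def write_isic_csv(path: Path, items: Iterable[tuple[str, str]]) -> None:
    """Write (image_id, class label) pairs in the ISIC 2018 CSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "MEL", "NV", "BKL"])
        for image_id, lbl in items:
            row = {"M": [1.0, 0.0, 0.0], "N": [0.0, 1.0, 0.0], "B": [0.0, 0.0, 1.0]}[lbl]
            writer.writerow([image_id] + [f"{v:.1f}" for v in row])


def write_split_manifest(path: Path, data: LabeledImageSet) -> None:
    if data.split is None:
        raise ValueError("dataset has no split")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "class", "split"])
        for image_id, _, lbl in data.items:
            writer.writerow([image_id, lbl, data.split[image_id]])
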