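"""Desk-scale stand-ins for dermoscopic data.

Two generators make every other module testable without any download:

* a parametric three-class lesion-image generator that renders
  class-coded blobs on a skin-toned background — nevus (N): smooth
  ellipse in uniform brown; melanoma (M): irregular star-like border,
  dual colouring and an off-center pale "regression" region; benign
  keratosis (B): sharply bounded, heavily textured plaque.  A
  ``separability`` dial in [0, 1] scales how distinguishable the classes
  are (1: visually disjoint; 0: pure noise).

* analytically specified mock classifiers whose outputs are drawn from
  per-true-class Dirichlet distributions, so routing behaviour can be
  engineered exactly (confusions, confidence levels) without training.

The generated label file uses the same ISIC-dialect CSV as real data.
These images deliberately mimic clinical cues (regression area, pale
veil analogue) so localization tests of the heat-maps are meaningful;
they are not photorealistic dermoscopy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from PIL import Image

from .preprocess import LabeledImageSet, write_isic_csv
from .routing import CLASSES, ClassifierBundle, OVA_NAMES, OVO_NAMES

__all__ = [
    "SyntheticConfig",
    "MockProfile",
    "TaggedSample",
    "generate_images",
    "write_image_dir",
    "make_mock_classifier",
    "mock_bundle",
    "identity_bundle",
    "confusable_bundle",
]

SKIN = np.array([224.0, 172.0, 150.0])
BROWN = np.array([130.0, 84.0, 52.0])
DARK = np.array([70.0, 42.0, 30.0])
BLUE_GRAY = np.array([110.0, 118.0, 140.0])
PALE = np.array([210.0, 190.0, 180.0])
TAN = np.array([176.0, 128.0, 88.0])


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of a synthetic dataset."""

    n_per_class: Mapping[str, int]
    image_size: int = 64
    separability: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must be in [0, 1]")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("n_per_class entries must be >= 1")


def _grid(size: int):
    y, x = np.mgrid[0:size, 0:size].astype(float)
    return (x - size / 2) / (size / 2), (y - size / 2) / (size / 2)


def _render_lesion(
    cls: str,
    size: int,
    rng: np.random.Generator,
    separability: float,
    center: tuple[float, float] = (0.0, 0.0),
    radius: float = 0.55,
) -> np.ndarray:
    """One HxWx3 uint8 lesion image; ``center``/``radius`` in [-1, 1] units."""
    noise_level = 1.0 - separability
    x, y = _grid(size)
    cx, cy = center
    cx += rng.uniform(-0.08, 0.08) * (1 + noise_level)
    cy += rng.uniform(-0.08, 0.08) * (1 + noise_level)
    dx, dy = x - cx, y - cy
    theta = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)

    img = np.empty((size, size, 3))
    img[...] = SKIN + rng.normal(0, 4, (size, size, 3))
    # gentle illumination gradient, as in real acquisition setups
    img += (x[..., None] * rng.uniform(-8, 8) + y[..., None] * rng.uniform(-8, 8))

    if cls == "N":  # smooth ellipse, uniform brown
        a = radius * rng.uniform(0.85, 1.0)
        b = a * rng.uniform(0.7, 0.95)
        mask = ((dx / a) ** 2 + (dy / b) ** 2) <= 1.0
        edge = np.clip(1.0 - ((dx / a) ** 2 + (dy / b) ** 2), 0, 1) ** 0.3
        color = BROWN + rng.normal(0, 6, 3)
        img[mask] = (edge[mask, None] * color + (1 - edge[mask, None]) * SKIN)
    elif cls == "M":  # irregular star border, dual color, pale regression
        k = rng.integers(5, 9)
        phase = rng.uniform(0, 2 * np.pi, 3)
        wobble = (
            0.22 * np.sin(k * theta + phase[0])
            + 0.12 * np.sin((k + 2) * theta + phase[1])
            + 0.08 * np.sin(3 * theta + phase[2])
        )
        boundary = radius * (1.0 + wobble)
        mask = r <= boundary
        half = np.sin(theta + rng.uniform(0, 2 * np.pi)) > 0
        color_map = np.where(half[..., None], DARK, BLUE_GRAY)
        img[mask] = color_map[mask] + rng.normal(0, 8, (int(mask.sum()), 3))
        # off-center pale regression area
        rcx, rcy = cx + rng.uniform(0.1, 0.25), cy + rng.uniform(-0.15, 0.15)
        reg = np.hypot(x - rcx, y - rcy) <= radius * 0.28
        img[reg & mask] = PALE + rng.normal(0, 5, (int((reg & mask).sum()), 3))
    elif cls == "B":  # sharply bounded textured plaque
        a = radius * rng.uniform(0.8, 0.95)
        mask = np.hypot(dx / a, dy / (a * rng.uniform(0.85, 1.0))) <= 1.0
        base = TAN + rng.normal(0, 5, 3)
        img[mask] = base
        # keratin-plug speckle texture: high-frequency multiplicative noise
        tex = rng.normal(0, 1, (size, size))
        tex = np.sign(tex) * (np.abs(tex) > 1.1)
        img[mask] += (tex[mask, None] * np.array([45.0, 40.0, 35.0]))
    else:
        raise ValueError(f"unknown class {cls!r}")

    img += rng.normal(0, 10 + 80 * noise_level, (size, size, 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_images(cfg: SyntheticConfig) -> LabeledImageSet:
    """Render the configured dataset; deterministic per seed."""
    items = []
    for cls in CLASSES:
        n = cfg.n_per_class.get(cls, 0)
        for i in range(n):
            rng = np.random.default_rng(
                [cfg.seed, CLASSES.index(cls), i]
            )
            img = _render_lesion(cls, cfg.image_size, rng, cfg.separability)
            items.append((f"SYN_{cls}_{i:05d}", img, cls))
    return LabeledImageSet(items)


def lesion_in_quadrant(
    cls: str, size: int, quadrant: str, seed: int = 0, separability: float = 1.0
) -> np.ndarray:
    """A lesion confined to one image quadrant ("tl","tr","bl","br")."""
    centers = {"tl": (-0.5, -0.5), "tr": (0.5, -0.5),
               "bl": (-0.5, 0.5), "br": (0.5, 0.5)}
    rng = np.random.default_rng(seed)
    return _render_lesion(cls, size, rng, separability,
                          center=centers[quadrant], radius=0.3)


def write_image_dir(data: LabeledImageSet, out_dir: Path) -> Path:
    """Write PNG images plus the ISIC-dialect ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for image_id, img, _ in data.items:
        Image.fromarray(img).save(out_dir / f"{image_id}.png")
    csv_path = out_dir / "ground_truth.csv"
    write_isic_csv(csv_path, [(i, c) for i, _, c in data.items])
    return csv_path


# ---------------------------------------------------------------------------
# Mock classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaggedSample:
    """An input carrying its ground truth, for mock classifiers."""

    sample_id: str
    true_class: str
    image: Optional[np.ndarray] = None


@dataclass(frozen=True)
class MockProfile:
    """Conditional output distribution of a mock player.

    ``conditional`` maps each true class to either a Dirichlet
    concentration vector over the player's output classes, or (when
    ``deterministic``) to the exact probability vector to emit.
    """

    conditional: Mapping[str, Sequence[float]]
    deterministic: bool = False

    def __post_init__(self) -> None:
        for cls, vec in self.conditional.items():
            arr = np.asarray(vec, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"profile for {cls!r} has negative entries")
            if self.deterministic and abs(arr.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"deterministic profile for {cls!r} must sum to 1"
                )


class MockClassifier:
    """Analytically specified player obeying the bundle contract."""

    def __init__(self, name: str, classes: Sequence[str],
                 profile: MockProfile, seed: int):
        self.name = name
        self.classes = tuple(classes)
        self.profile = profile
        self.seed = seed

    def predict_proba(self, x) -> np.ndarray:
        vec = np.asarray(self.profile.conditional[x.true_class], dtype=float)
        if self.profile.deterministic:
            return vec
        # reproducible per (seed, sample, player)
        rng = np.random.default_rng(
            [self.seed,
             zlib.crc32(x.sample_id.encode()),
             zlib.crc32(self.name.encode())]
        )
        return rng.dirichlet(vec)


def make_mock_classifier(name: str, classes: Sequence[str],
                         profile: MockProfile, seed: int = 0) -> MockClassifier:
    return MockClassifier(name, classes, profile, seed)


def _player_classes(name: str) -> tuple[str, ...]:
    if name == "s3":
        return CLASSES
    for c, n in OVA_NAMES.items():
        if n == name:
            return (c, "rest")
    for pair, n in OVO_NAMES.items():
        if n == name:
            return tuple(sorted(pair))
    raise KeyError(name)


def mock_bundle(profiles: Mapping[str, MockProfile], seed: int = 0) -> ClassifierBundle:
    members = {
        name: make_mock_classifier(name, _player_classes(name), prof, seed)
        for name, prof in profiles.items()
    }
    return ClassifierBundle(members)


def identity_bundle(seed: int = 0) -> ClassifierBundle:
    """Seven point-mass players that always reveal the true class."""
    profiles: dict[str, MockProfile] = {}
    profiles["s3"] = MockProfile(
        {c: np.eye(3)[i] for i, c in enumerate(CLASSES)}, deterministic=True
    )
    for c, name in OVA_NAMES.items():
        profiles[name] = MockProfile(
            {t: ([1.0, 0.0] if t == c else [0.0, 1.0]) for t in CLASSES},
            deterministic=True,
        )
    for pair, name in OVO_NAMES.items():
        a, b = sorted(pair)
        cond = {}
        for t in CLASSES:
            if t == a:
                cond[t] = [1.0, 0.0]
            elif t == b:
                cond[t] = [0.0, 1.0]
            else:  # the third class: the duel is uninformative
                cond[t] = [0.5, 0.5]
        profiles[name] = MockProfile(cond, deterministic=True)
    return mock_bundle(profiles, seed)


def confusable_bundle(seed: int = 0) -> ClassifierBundle:
    """Engineered error structure: the 3-class player confuses melanoma
    with keratosis, the ova players disagree with it there (pushing those
    samples out of the high-confidence group), and the B/M duel resolves
    the confusion.  Nevi are easy for everyone.

    With thresholds such as (0.1, 0.5) the full framework corrects most
    M<->B errors of the 3-class player, so framework BACC exceeds the
    3-class player's own BACC — the scaled-down analogue of the gain the
    hierarchical design targets.
    """
    profiles: dict[str, MockProfile] = {}
    # s3: melanoma and keratosis land near the B/M decision boundary
    profiles["s3"] = MockProfile({
        "B": [12.0, 10.0, 1.0],
        "M": [10.0, 12.0, 1.0],
        "N": [1.0, 1.0, 30.0],
    })
    # ova players: accurate and confident
    for c, name in OVA_NAMES.items():
        profiles[name] = MockProfile(
            {t: ([50.0, 2.0] if t == c else [2.0, 50.0]) for t in CLASSES}
        )
    # ovo players: accurate on their own pair, uninformative otherwise
    for pair, name in OVO_NAMES.items():
        a, b = sorted(pair)
        cond = {}
        for t in CLASSES:
            if t == a:
                cond[t] = [50.0, 2.0]
            elif t == b:
                cond[t] = [2.0, 50.0]
            else:
                cond[t] = [5.0, 5.0]
        profiles[name] = MockProfile(cond)
    return mock_bundle(profiles, seed)
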