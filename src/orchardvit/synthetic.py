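"""Seeded generator of labeled fruit-like RGB images and dataset trees.

The generator emulates the statistical structure of three orchard image
collections without any photographic data:

* **afvc** — 85 variety classes told apart by fruit hue/shape/texture
  (315 train / 35 test images per class, 29,750 total);
* **afqc** — fresh vs rotten fruit, told apart by lesion coverage
  (1,044 train / 116 test per class, 2,320 total);
* **afdc/adec** — seven disease phenotypes (blotch, brown rot, cork
  spots, powdery mildew, rot, scab, plus normal), each rendered by a
  distinct lesion operator (2,682 train / 294 test total).

Every image is a deterministic function of its spec and an integer seed;
per-image seeds derive from one master seed through
``numpy.random.SeedSequence([master_seed, class_idx, split_idx, img_idx])``
so any subset can be regenerated independently and byte-identically.
Images are synthetic renderings (ellipse + procedural lesions on a
cluttered background), not photorealistic: they carry learnable color,
shape and texture signal, nothing more.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "LESION_KINDS",
    "DatasetDesign",
    "FruitImageSpec",
    "render_fruit",
    "design_presets",
    "imbalance_design",
    "default_class_specs",
    "variety_specs",
    "generate_dataset",
    "load_dataset_arrays",
]

LESION_KINDS = ("none", "blotch", "brown_rot", "cork_spot", "powdery_mildew", "rot", "scab")

ADEC_CLASSES = (
    "apple_blotch",
    "apple_brown_rot",
    "apple_cork_spots",
    "apple_powdery_mildew",
    "apple_rot",
    "apple_scab",
    "apple_normal",
)


@dataclass
class DatasetDesign:
    """Class list with per-class train/test counts and image size."""

    name: str
    classes: list[str]
    per_class_train: list[int]
    per_class_test: list[int]
    image_size: int = 96

    def __post_init__(self) -> None:
        if isinstance(self.per_class_train, int):
            self.per_class_train = [self.per_class_train] * len(self.classes)
        if isinstance(self.per_class_test, int):
            self.per_class_test = [self.per_class_test] * len(self.classes)
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class labels must be unique")
        if len(self.per_class_train) != len(self.classes) or len(self.per_class_test) != len(self.classes):
            raise ValueError("per-class count lists must match the class list")
        if any(c < 0 for c in self.per_class_train + self.per_class_test):
            raise ValueError("counts must be non-negative")

    @property
    def train_total(self) -> int:
        return int(sum(self.per_class_train))

    @property
    def test_total(self) -> int:
        return int(sum(self.per_class_test))

    @property
    def total(self) -> int:
        return self.train_total + self.test_total


@dataclass
class FruitImageSpec:
    """Appearance parameters of one class of synthetic fruit images.

    ``base_hue`` is degrees on the color wheel; ``lesion_severity`` is the
    approximate fraction of fruit area the lesion operator covers;
    ``background_clutter`` and ``noise_sd`` control distractor texture and
    pixel noise (both in [0, 1] image units).
    """

    base_hue: float = 10.0
    shape_eccentricity: float = 0.15
    lesion_kind: str = "none"
    lesion_severity: float = 0.0
    background_clutter: float = 0.3
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_hue < 360.0:
            raise ValueError("base_hue must lie in [0, 360)")
        if not 0.0 <= self.lesion_severity <= 1.0:
            raise ValueError("lesion_severity must lie in [0, 1]")
        if self.lesion_kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.lesion_kind!r}")


def _smooth_noise(rng, size: int, scale: int) -> np.ndarray:
    """Low-frequency noise field in [0, 1] via coarse grid + bilinear upsampling."""
    coarse = rng.random((scale, scale))
    im = Image.fromarray((coarse * 255).astype(np.uint8))
    up = np.asarray(im.resize((size, size), Image.BILINEAR), dtype=np.float64) / 255.0
    return up


def render_fruit(spec: FruitImageSpec, rng_seed: int, size: int = 96,
                 return_mask: bool = False):
    """Render one synthetic fruit image; deterministic in (spec, seed).

    Returns an ``size x size x 3`` uint8 array (and the boolean fruit mask
    when ``return_mask``).  The lesion operator is applied only when
    ``lesion_severity > 0``, so zero severity renders identically to
    ``lesion_kind="none"`` at the same seed.
    """
    rng = np.random.default_rng(rng_seed)
    s = size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    # background: grey-green gradient + clutter blobs
    base = 0.35 + 0.1 * (yy / s)
    img = np.stack([base * 0.8, base, base * 0.7], axis=-1)
    clutter = _smooth_noise(rng, s, 6)
    img += spec.background_clutter * 0.5 * (clutter[..., None] - 0.5)

    # fruit ellipse, slightly off-center, random orientation
    cy = s * (0.5 + 0.05 * rng.standard_normal())
    cx = s * (0.5 + 0.05 * rng.standard_normal())
    theta = rng.uniform(0, np.pi)
    ecc = spec.shape_eccentricity
    ry = s * 0.33 * (1.0 + ecc * rng.uniform(0.5, 1.0))
    rx = s * 0.33 * (1.0 - ecc * rng.uniform(0.5, 1.0))
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r2 = (u / rx) ** 2 + (v / ry) ** 2
    mask = r2 <= 1.0

    hue = (spec.base_hue + rng.uniform(-5, 5)) % 360.0
    sat = rng.uniform(0.65, 0.85)
    val = rng.uniform(0.7, 0.9)
    fruit_rgb = np.array(colorsys.hsv_to_rgb(hue / 360.0, sat, val))
    shading = np.clip(1.0 - 0.45 * r2, 0.3, 1.0)  # radial light falloff
    speckle = 0.06 * (_smooth_noise(rng, s, 12) - 0.5)  # skin texture
    fruit = fruit_rgb[None, None, :] * (shading + speckle)[..., None]
    img = np.where(mask[..., None], fruit, img)

    if spec.lesion_kind != "none" and spec.lesion_severity > 0:
        severity = spec.lesion_severity * rng.uniform(0.75, 1.25)
        severity = float(np.clip(severity, 0.0, 1.0))
        img = _apply_lesion(img, mask, spec.lesion_kind, severity, rng, (u, v, rx, ry))

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    out = (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    if return_mask:
        return out, mask
    return out


def _apply_lesion(img, mask, kind, severity, rng, geom):
    """Apply one lesion operator over (approximately) ``severity`` of the fruit."""
    u, v, rx, ry = geom
    s = img.shape[0]
    r2 = (u / rx) ** 2 + (v / ry) ** 2

    if kind in ("rot", "brown_rot"):
        # one expanding region from an interior focus; radius set so
        # area ~= severity * fruit area
        fu, fv = rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4)
        d2 = ((u / rx) - fu) ** 2 + ((v / ry) - fv) ** 2
        lesion = mask & (d2 <= severity)
        color = np.array([0.35, 0.2, 0.08]) if kind == "rot" else np.array([0.5, 0.28, 0.1])
        edge = np.clip(1.0 - d2 / max(severity, 1e-9), 0.0, 1.0) ** 0.5
        alpha = np.where(lesion, 0.55 + 0.45 * edge, 0.0)
    elif kind == "blotch":
        # irregular dark patches from thresholded low-frequency noise
        f = _smooth_noise(rng, s, 9)
        thr = np.quantile(f[mask], 1.0 - severity) if mask.any() else 1.0
        lesion = mask & (f >= thr)
        color = np.array([0.22, 0.14, 0.08])
        alpha = np.where(lesion, 0.85, 0.0)
    elif kind == "scab":
        # many small dark dots
        target = severity * mask.sum()
        dots = np.zeros_like(mask)
        area = 0.0
        for _ in range(400):
            if area >= target:
                break
            dy, dx = rng.integers(0, s, size=2)
            if not mask[dy, dx]:
                continue
            rad = rng.uniform(1.0, 2.5)
            dd = (np.arange(s)[:, None] - dy) ** 2 + (np.arange(s)[None, :] - dx) ** 2
            new = mask & (dd <= rad**2)
            dots |= new
            area = dots.sum()
        lesion = dots
        color = np.array([0.15, 0.12, 0.08])
        alpha = np.where(lesion, 0.9, 0.0)
    elif kind == "cork_spot":
        # medium dimpled spots: darkened rim, lightened sunken center
        target = severity * mask.sum()
        out = img.copy()
        area = 0.0
        for _ in range(80):
            if area >= target:
                break
            dy, dx = rng.integers(0, s, size=2)
            if not mask[dy, dx]:
                continue
            rad = rng.uniform(2.0, 4.0)
            dd = np.sqrt((np.arange(s)[:, None] - dy) ** 2 + (np.arange(s)[None, :] - dx) ** 2)
            spot = mask & (dd <= rad)
            rim = spot & (dd >= rad * 0.6)
            out[rim] = out[rim] * 0.45
            center = spot & (dd < rad * 0.6)
            out[center] = np.clip(out[center] * 1.15 + 0.05, 0, 1)
            area += spot.sum()
        return out
    elif kind == "powdery_mildew":
        # pale fungal overlay, strongest where the texture field is high
        f = _smooth_noise(rng, s, 10)
        alpha = np.where(mask, severity * np.clip(0.3 + 0.7 * f, 0, 1), 0.0)
        color = np.array([0.92, 0.92, 0.88])
    else:  # pragma: no cover
        raise ValueError(f"unknown lesion kind {kind!r}")

    return img * (1.0 - alpha[..., None]) + color[None, None, :] * alpha[..., None]


# -- designs ------------------------------------------------------------------


def design_presets(name: str, image_size: int = 96) -> DatasetDesign:
    """The three built-in dataset designs.

    ``afvc``: 85 classes x (315 train + 35 test) = 29,750 images;
    ``afqc``: 2 classes x (1,044 + 116) = 2,320;
    ``adec``: 7 classes, 2,682 train + 294 test = 2,976.
    """
    name = name.lower()
    if name == "afvc":
        classes = [f"variety_{i:02d}" for i in range(85)]
        return DatasetDesign("afvc", classes, 315, 35, image_size)
    if name == "afqc":
        return DatasetDesign("afqc", ["fresh", "rotten"], 1044, 116, image_size)
    if name == "adec":
        train = [383] * 6 + [384]  # totals 2,682; per-class split is a design choice
        test = [42] * 7  # totals 294
        return DatasetDesign("adec", list(ADEC_CLASSES), train, test, image_size)
    raise ValueError(f"unknown preset {name!r}; choose from afvc, afqc, adec")


def imbalance_design(
    n_classes: int,
    majority_count: int,
    minority_count: int,
    minority_fraction_of_classes: float = 0.5,
    test_per_class: int = 32,
    image_size: int = 96,
) -> DatasetDesign:
    """A deliberately imbalanced design for loss-comparison experiments.

    The stated fraction of classes (at least one) receives
    ``minority_count`` training images, the rest ``majority_count``; the
    test split stays balanced so minority-class recall is measurable.
    """
    if not 0.0 < minority_fraction_of_classes < 1.0:
        raise ValueError("minority_fraction_of_classes must lie in (0, 1)")
    if majority_count <= 0 or minority_count <= 0:
        raise ValueError("counts must be positive")
    n_minority = max(1, round(n_classes * minority_fraction_of_classes))
    n_minority = min(n_minority, n_classes - 1)
    classes = [f"class_{i}" for i in range(n_classes)]
    train = [majority_count] * (n_classes - n_minority) + [minority_count] * n_minority
    return DatasetDesign("imbalance", classes, train, test_per_class, image_size)


def variety_specs(classes, hue_start: float = 0.0, clutter: float = 0.3,
                  noise_sd: float = 0.02) -> dict[str, FruitImageSpec]:
    """Hue-separated lesion-free specs, one per class, evenly on the wheel."""
    n = len(classes)
    return {
        c: FruitImageSpec(base_hue=(hue_start + 360.0 * i / n) % 360.0,
                          background_clutter=clutter, noise_sd=noise_sd)
        for i, c in enumerate(classes)
    }


def default_class_specs(design: DatasetDesign, easy: bool = False) -> dict[str, FruitImageSpec]:
    """Per-class image specs matching a design's semantics.

    Variety-style classes get distinct hues; ``fresh``/``rotten`` differ by
    rot coverage; disease-named classes get their lesion operator.  Easy
    mode lowers clutter/noise for fast-converging tests.
    """
    clutter, noise = (0.1, 0.01) if easy else (0.3, 0.02)
    specs: dict[str, FruitImageSpec] = {}
    kinds = {
        "apple_blotch": "blotch", "apple_brown_rot": "brown_rot",
        "apple_cork_spots": "cork_spot", "apple_powdery_mildew": "powdery_mildew",
        "apple_rot": "rot", "apple_scab": "scab", "apple_normal": "none",
    }
    n = len(design.classes)
    for i, c in enumerate(design.classes):
        if c in kinds:
            kind = kinds[c]
            specs[c] = FruitImageSpec(
                base_hue=15.0, lesion_kind=kind,
                lesion_severity=0.0 if kind == "none" else 0.4,
                background_clutter=clutter, noise_sd=noise,
            )
        elif c == "fresh":
            specs[c] = FruitImageSpec(base_hue=10.0, background_clutter=clutter, noise_sd=noise)
        elif c == "rotten":
            specs[c] = FruitImageSpec(base_hue=10.0, lesion_kind="rot", lesion_severity=0.5,
                                      background_clutter=clutter, noise_sd=noise)
        else:
            specs[c] = FruitImageSpec(base_hue=(360.0 * i / n) % 360.0,
                                      background_clutter=clutter, noise_sd=noise)
    return specs


# -- dataset emission ---------------------------------------------------------

_SPLIT_CODE = {"train": 0, "test": 1}


def image_seed(master_seed: int, class_idx: int, split: str, image_idx: int) -> int:
    """Per-image seed derivation (counter-based, subset-stable)."""
    ss = np.random.SeedSequence([int(master_seed), class_idx, _SPLIT_CODE[split], image_idx])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(
    design: DatasetDesign,
    class_spec_map: Mapping[str, FruitImageSpec] | None,
    out_dir,
    master_seed: int,
    overwrite: bool = False,
    manifest_only: bool = False,
) -> pd.DataFrame:
    """Emit a directory-per-class dataset tree and return its manifest.

    Layout: ``OUT/{train,test}/{class_label}/img_#####.png``; the manifest
    (also written to ``OUT/manifest.csv``) has one row per image with
    columns ``path, label, split, seed``.  With ``manifest_only`` no PNG
    is rendered — counts and seeds are still exact, which is enough for
    design-audit work on large presets.
    """
    out_dir = Path(out_dir)
    if class_spec_map is None:
        class_spec_map = default_class_specs(design)
    missing = [c for c in design.classes if c not in class_spec_map]
    if missing:
        raise ValueError(f"class_spec_map lacks specs for {missing}")
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True to proceed")
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for ci, label in enumerate(design.classes):
        for split, count in (("train", design.per_class_train[ci]),
                             ("test", design.per_class_test[ci])):
            cls_dir = out_dir / split / label
            if not manifest_only:
                cls_dir.mkdir(parents=True, exist_ok=True)
            for i in range(count):
                seed = image_seed(master_seed, ci, split, i)
                rel = f"{split}/{label}/img_{i:05d}.png"
                if not manifest_only:
                    img = render_fruit(class_spec_map[label], seed, size=design.image_size)
                    Image.fromarray(img).save(out_dir / rel, format="PNG")
                rows.append((rel, label, split, seed))
    manifest = pd.DataFrame(rows, columns=["path", "label", "split", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset_arrays(data_dir, split: str):
    """Read one split of a generated dataset into arrays.

    Returns ``(X, y, class_names)`` with ``X`` of shape (n, H, W, 3) in
    [0, 1] and ``y`` integer class indices into ``class_names``.
    """
    split_dir = Path(data_dir) / split
    if not split_dir.is_dir():
        raise FileNotFoundError(f"missing split directory {split_dir}")
    class_names = sorted(p.name for p in split_dir.iterdir() if p.is_dir())
    X, y = [], []
    for ci, label in enumerate(class_names):
        for f in sorted((split_dir / label).glob("*.png")):
            X.append(np.asarray(Image.open(f).convert("RGB"), dtype=np.float64) / 255.0)
            y.append(ci)
    if not X:
        raise FileNotFoundError(f"no images under {split_dir}")
    return np.stack(X), np.asarray(y), class_names
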