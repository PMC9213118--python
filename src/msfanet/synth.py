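"""Seeded synthetic dermoscopy-image generator.

Real dermoscopy lesions come in three troublesome morphologies: small
high-contrast targets, large prominent-shape targets, and targets with
irregular edges.  The generator emulates all three as darker elliptical
blobs whose radius is modulated by seeded low-frequency angular noise
(largest amplitude for the irregular-edge category), painted on a
skin-toned, lightly textured background, optionally crossed by thin dark
hair-line arcs.  Each image is paired with the exact binary mask of the
analytic lesion region, so generated data exercise every mechanical part of
the pipeline without external downloads.

The lesion region is star-shaped about its centre (the modulated radius is a
single-valued function of the polar angle), which guarantees a connected
foreground.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import bezier_curve

__all__ = ["SyntheticSpec", "CATEGORY_DEFAULTS", "generate_synthetic_lesion",
           "generate_arrays", "generate_dataset"]

CATEGORIES = ("small", "prominent", "irregular_edge")

# (area fraction range, boundary noise amplitude) per morphology
CATEGORY_DEFAULTS: dict[str, tuple[tuple[float, float], float]] = {
    "small": ((0.005, 0.05), 0.08),
    "prominent": ((0.15, 0.45), 0.08),
    "irregular_edge": ((0.08, 0.30), 0.35),
}

_SKIN_RGB = np.array([0.80, 0.60, 0.52])
_LESION_RGB = np.array([0.42, 0.28, 0.22])


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic lesion image."""

    category: str = "prominent"
    image_size: tuple[int, int] = (224, 224)
    area_fraction_range: tuple[float, float] | None = None
    boundary_noise_amplitude: float | None = None
    hair_artifact_probability: float = 0.3
    color_jitter: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, "
                             f"got {self.category!r}")
        default_range, default_amp = CATEGORY_DEFAULTS[self.category]
        if self.area_fraction_range is None:
            self.area_fraction_range = default_range
        if self.boundary_noise_amplitude is None:
            self.boundary_noise_amplitude = default_amp
        lo, hi = self.area_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"invalid area fraction range ({lo}, {hi})")
        h, w = self.image_size
        if lo * h * w < 4:
            raise ValueError(
                f"area range ({lo}, {hi}) infeasible for image size {h}x{w}")


def _lesion_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    lo, hi = spec.area_fraction_range
    target = rng.uniform(lo, hi)
    cy = rng.uniform(0.35, 0.65) * h
    cx = rng.uniform(0.35, 0.65) * w
    aspect = rng.uniform(0.6, 1.0)
    phi = rng.uniform(0.0, np.pi)
    amp = spec.boundary_noise_amplitude
    harmonics = [(k, *rng.normal(0.0, 1.0, 2)) for k in range(2, 6)]

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    theta = np.arctan2(v / aspect, u)
    m = np.ones_like(theta)
    for k, a, b in harmonics:
        m += amp * (a * np.cos(k * theta) + b * np.sin(k * theta)) / 2.0
    m = np.clip(m, 0.25, None)

    r0 = np.sqrt(target * h * w / (np.pi * aspect))
    rho = np.sqrt(u ** 2 + (v / aspect) ** 2)
    mask = None
    # two fixed-point corrections pull the measured area onto the target
    for _ in range(3):
        mask = rho <= r0 * m
        frac = mask.mean()
        if frac <= 0:
            r0 *= 1.5
            continue
        r0 *= np.sqrt(target / frac)
    mask = rho <= r0 * m
    return mask.astype(np.uint8)


def generate_synthetic_lesion(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (image, mask) pair.

    Returns an H x W x 3 uint8 RGB image and an H x W uint8 mask in {0, 1}.
    The same spec (including seed) always yields a bit-identical pair.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    lo, hi = spec.area_fraction_range

    mask = None
    for _attempt in range(6):
        candidate = _lesion_mask(spec, rng)
        if lo <= candidate.mean() <= hi:
            mask = candidate
            break
    if mask is None:
        raise ValueError(
            f"could not realise an area fraction in ({lo}, {hi}) "
            f"at image size {h}x{w}")

    skin = _SKIN_RGB + rng.uniform(-spec.color_jitter, spec.color_jitter, 3)
    lesion = _LESION_RGB + rng.uniform(-spec.color_jitter, spec.color_jitter, 3)
    img = np.empty((h, w, 3))
    img[:] = skin
    # mild low-frequency skin texture
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=4.0)
    img += 0.04 * texture[..., None]
    # lesion fill with its own mottled texture
    lesion_tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=2.0)
    fill = lesion[None, None, :] + 0.05 * lesion_tex[..., None]
    img = np.where(mask[..., None].astype(bool), fill, img)

    if rng.random() < spec.hair_artifact_probability:
        for _ in range(rng.integers(1, 4)):
            r0c, c0c = rng.integers(0, h), rng.integers(0, w)
            r1c, c1c = rng.integers(0, h), rng.integers(0, w)
            r2c, c2c = rng.integers(0, h), rng.integers(0, w)
            rr, cc = bezier_curve(r0c, c0c, r1c, c1c, r2c, c2c,
                                  weight=1.0, shape=(h, w))
            img[rr, cc] = 0.12

    img = ndimage.gaussian_filter(img, sigma=(0.8, 0.8, 0))
    img += rng.normal(0.0, 0.01, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return (img * 255).round().astype(np.uint8), mask


def _category_sequence(n: int, category_mix: dict[str, float],
                       rng: np.random.Generator) -> list[str]:
    cats = [c for c in CATEGORIES if category_mix.get(c, 0) > 0]
    if not cats:
        raise ValueError("category_mix selects no categories")
    weights = np.array([category_mix[c] for c in cats], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * n).astype(int)
    # distribute the remainder by largest fractional part
    remainder = n - counts.sum()
    order = np.argsort(-(weights * n - counts))
    for i in range(remainder):
        counts[order[i % len(cats)]] += 1
    seq = [c for c, k in zip(cats, counts) for _ in range(k)]
    rng.shuffle(seq)
    return seq


def generate_arrays(n: int, category_mix: dict[str, float] | None = None,
                    image_size: tuple[int, int] = (64, 64), seed: int = 0,
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Generate ``n`` pairs in memory.

    Returns (images N x H x W x 3 uint8, masks N x H x W uint8, categories).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    category_mix = category_mix or {c: 1.0 for c in CATEGORIES}
    rng = np.random.default_rng(seed)
    cats = _category_sequence(n, category_mix, rng)
    images = np.empty((n, *image_size, 3), dtype=np.uint8)
    masks = np.empty((n, *image_size), dtype=np.uint8)
    for i, cat in enumerate(cats):
        child = int(rng.integers(2 ** 31))
        img, msk = generate_synthetic_lesion(
            SyntheticSpec(category=cat, image_size=image_size, seed=child))
        images[i], masks[i] = img, msk
    return images, masks, cats


def generate_dataset(root: str | Path, n: int,
                     category_mix: dict[str, float] | None = None,
                     image_size: tuple[int, int] = (224, 224),
                     seed: int = 0) -> pd.DataFrame:
    """Write ``n`` PNG image/mask pairs in ISIC-style layout plus a manifest.

    Layout: ``root/images/synth_XXXX.png`` and
    ``root/masks/synth_XXXX_segmentation.png``; the manifest CSV records
    filename, category, measured lesion area fraction and the per-image seed.
    Regeneration with the same arguments reproduces identical files.
    """
    if n < 3:
        raise ValueError("n must be >= 3 so the dataset can be split")
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    category_mix = category_mix or {c: 1.0 for c in CATEGORIES}
    rng = np.random.default_rng(seed)
    cats = _category_sequence(n, category_mix, rng)
    rows = []
    for i, cat in enumerate(cats):
        child = int(rng.integers(2 ** 31))
        img, msk = generate_synthetic_lesion(
            SyntheticSpec(category=cat, image_size=image_size, seed=child))
        stem = f"synth_{i:04d}"
        Image.fromarray(img).save(root / "images" / f"{stem}.png")
        Image.fromarray(msk * 255).save(root / "masks" / f"{stem}_segmentation.png")
        rows.append({"filename": f"{stem}.png", "category": cat,
                     "area_fraction": float(msk.mean()), "seed": child})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
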