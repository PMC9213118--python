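"""Dataset discovery, train/val/test splitting, preprocessing, augmentation.

The expected on-disk layout is ISIC-style: an ``images/`` directory of
JPEG/PNG dermoscopy photographs and a ``masks/`` directory of single-channel
PNG lesion masks whose stems match the image stems (an ``_segmentation``
suffix on the mask is tolerated, as in the ISIC archives).

Preprocessing resizes to a square working resolution (default 224),
bilinear for images and nearest-neighbour for masks so masks stay binary,
and standardizes each colour channel.  Normalization statistics default to
values computed from the training split; fixed ImageNet-style constants are
available for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

__all__ = ["DatasetSplit", "split_pairs", "kfold_splits", "load_isic_dataset",
           "compute_normalization", "preprocess", "augment", "load_pairs",
           "IMAGENET_MEAN", "IMAGENET_STD", "DEFAULT_FRACTIONS"]

IMAGE_EXTS = (".png", ".jpg", ".jpeg")
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

# 1814 / 260 / 520 out of 2594
DEFAULT_FRACTIONS = (1814 / 2594, 260 / 2594, 520 / 2594)


@dataclass
class DatasetSplit:
    """Disjoint train/val/test lists of (image path, mask path) pairs."""

    train: list[tuple[Path, Path]]
    val: list[tuple[Path, Path]]
    test: list[tuple[Path, Path]]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        seen = set()
        for part in (self.train, self.val, self.test):
            for img, _ in part:
                if img in seen:
                    raise ValueError(f"pair {img} appears in more than one split")
                seen.add(img)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.val), len(self.test))


def split_pairs(pairs: list, fractions=DEFAULT_FRACTIONS,
                seed: int = 0) -> DatasetSplit:
    """Seeded shuffle followed by a rounded three-way split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    n = len(pairs)
    if n == 0:
        raise ValueError("no pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [pairs[i] for i in order]
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    return DatasetSplit(train=shuffled[:n_train],
                        val=shuffled[n_train:n_train + n_val],
                        test=shuffled[n_train + n_val:],
                        fractions=tuple(fractions))


def kfold_splits(pairs: list, k: int = 5, seed: int = 0):
    """Seeded k-fold cross-validation splits.

    Yields k (train_pairs, val_pairs) tuples with disjoint validation folds
    covering every pair exactly once.
    """
    if k < 2 or k > len(pairs):
        raise ValueError(f"k must be in [2, n_pairs], got k={k} for "
                         f"{len(pairs)} pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds = np.array_split(order, k)
    for i in range(k):
        val_idx = set(folds[i].tolist())
        train = [pairs[j] for j in order if j not in val_idx]
        val = [pairs[j] for j in folds[i]]
        yield train, val


def _find_mask(stem: str, mask_dir: Path) -> Path | None:
    for suffix in ("_segmentation", ""):
        for ext in IMAGE_EXTS:
            cand = mask_dir / f"{stem}{suffix}{ext}"
            if cand.exists():
                return cand
    return None


def load_isic_dataset(root: str | Path, fractions=DEFAULT_FRACTIONS,
                      seed: int = 0) -> DatasetSplit:
    """Discover image/mask pairs under ``root`` and split them."""
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    images = sorted(p for p in img_dir.iterdir()
                    if p.suffix.lower() in IMAGE_EXTS)
    if not images:
        raise ValueError(f"no images found under {img_dir}")
    pairs = []
    for img in images:
        mask = _find_mask(img.stem, mask_dir)
        if mask is None:
            raise FileNotFoundError(f"no mask found for image stem {img.stem!r}")
        pairs.append((img, mask))
    return split_pairs(pairs, fractions, seed)


def _to_rgb_array(image) -> np.ndarray:
    """Coerce a path / PIL image / array to H x W x 3 float in [0, 1]."""
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        if image.mode != "RGB":
            if image.mode in ("RGBA", "L", "P"):
                image = image.convert("RGB")
            else:
                raise ValueError(f"unsupported image mode {image.mode!r}")
        image = np.asarray(image)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    if image.dtype == np.uint8:
        image = image.astype(np.float64) / 255.0
    return image.astype(np.float64)


def _to_mask_array(mask) -> np.ndarray:
    if isinstance(mask, (str, Path)):
        mask = Image.open(mask)
    if isinstance(mask, Image.Image):
        mask = np.asarray(mask.convert("L"))
    mask = np.asarray(mask)
    if mask.ndim == 3:
        if mask.shape[2] != 1:
            raise ValueError(f"mask must be single-channel, got shape {mask.shape}")
        mask = mask[..., 0]
    if mask.dtype == np.uint8:
        # 0/255 PNG masks threshold at mid-scale; 0/1 arrays pass through
        thresh = 127 if mask.max() > 1 else 0
    else:
        thresh = 0.5
    return (mask > thresh).astype(np.uint8)


def compute_normalization(images) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std (in [0, 1] units) over an iterable of images."""
    s = np.zeros(3)
    s2 = np.zeros(3)
    n = 0
    for image in images:
        arr = _to_rgb_array(image)
        s += arr.sum(axis=(0, 1))
        s2 += (arr ** 2).sum(axis=(0, 1))
        n += arr.shape[0] * arr.shape[1]
    if n == 0:
        raise ValueError("no images supplied")
    mean = s / n
    std = np.sqrt(np.maximum(s2 / n - mean ** 2, 1e-12))
    return mean, std


def preprocess(image, mask=None, size: int = 224,
               mean: np.ndarray | None = None, std: np.ndarray | None = None):
    """Resize and normalize one (image, mask) pair.

    Returns a ``size x size x 3`` float32 tensor (channel-standardized) and,
    if a mask was given, a ``size x size x 1`` uint8 tensor in {0, 1}.
    Bilinear resampling for the image, nearest-neighbour for the mask.
    Without explicit statistics, ImageNet-style constants are applied.
    """
    arr = _to_rgb_array(image)
    pil = Image.fromarray((arr * 255).round().astype(np.uint8))
    arr = np.asarray(pil.resize((size, size), Image.BILINEAR),
                     dtype=np.float64) / 255.0
    mean = IMAGENET_MEAN if mean is None else np.asarray(mean, dtype=np.float64)
    std = IMAGENET_STD if std is None else np.asarray(std, dtype=np.float64)
    tensor = ((arr - mean) / std).astype(np.float32)
    if mask is None:
        return tensor
    m = _to_mask_array(mask)
    mp = Image.fromarray(m * 255)
    m = (np.asarray(mp.resize((size, size), Image.NEAREST)) > 127).astype(np.uint8)
    return tensor, m[..., None]


def _center_crop_resize(arr: np.ndarray, scale: float, order: int) -> np.ndarray:
    if scale >= 1.0:
        return arr
    h, w = arr.shape[:2]
    ch, cw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
    top, left = (h - ch) // 2, (w - cw) // 2
    crop = arr[top:top + ch, left:left + cw]
    zoom = [h / ch, w / cw] + [1] * (arr.ndim - 2)
    out = ndimage.zoom(crop, zoom, order=order, grid_mode=True, mode="nearest")
    # guard against off-by-one from rounding inside zoom
    return out[:h, :w]


def augment(image: np.ndarray, mask: np.ndarray, seed,
            rotation_deg: float = 30.0,
            crop_scale: tuple[float, float] = (0.8, 1.0),
            jitter: float = 0.2):
    """Seeded paired augmentation.

    The same rotation and centre crop are applied to image and mask (the
    mask with nearest-neighbour resampling so it stays binary); photometric
    jitter (brightness, contrast, saturation, hue) touches the image only.
    ``seed`` may be an integer or a ``numpy.random.Generator``.  With
    ``rotation_deg=0``, ``crop_scale=(1, 1)`` and ``jitter=0`` the pair is
    returned unchanged.
    """
    rng = seed if hasattr(seed, "uniform") else np.random.default_rng(seed)
    img = _to_rgb_array(image)
    msk = _to_mask_array(mask)
    if img.shape[:2] != msk.shape[:2]:
        raise ValueError(
            f"image {img.shape} and mask {msk.shape} disagree on spatial size")

    angle = rng.uniform(-rotation_deg, rotation_deg)
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant")

    scale = rng.uniform(*crop_scale)
    if scale < 1.0:
        img = _center_crop_resize(img, scale, order=1)
        msk = _center_crop_resize(msk, scale, order=0)

    if jitter > 0:
        brightness = 1.0 + rng.uniform(-jitter, jitter)
        contrast = 1.0 + rng.uniform(-jitter, jitter)
        saturation = 1.0 + rng.uniform(-jitter, jitter)
        hue_shift = rng.uniform(-jitter / 2.0, jitter / 2.0)
        img = img * brightness
        m = img.mean()
        img = m + (img - m) * contrast
        gray = img.mean(axis=2, keepdims=True)
        img = gray + (img - gray) * saturation
        img = np.clip(img, 0.0, 1.0)
        hsv = rgb2hsv(img)
        hsv[..., 0] = (hsv[..., 0] + hue_shift) % 1.0
        img = hsv2rgb(hsv)

    return np.clip(img, 0.0, 1.0), (msk > 0).astype(np.uint8)


def load_pairs(pairs, size: int = 224, mean=None, std=None,
               augment_seed=None, **augment_kwargs):
    """Load (image, mask) path pairs into model-ready arrays.

    Returns float32 images (N, size, size, 3) and uint8 masks (N, size,
    size, 1).  When ``augment_seed`` is given, each pair is augmented before
    preprocessing.
    """
    xs, ys = [], []
    rng = None
    if augment_seed is not None:
        rng = augment_seed if isinstance(augment_seed, np.random.Generator) \
            else np.random.default_rng(augment_seed)
    for img_path, mask_path in pairs:
        img, msk = _to_rgb_array(img_path), _to_mask_array(mask_path)
        if rng is not None:
            img, msk = augment(img, msk, rng, **augment_kwargs)
        t, m = preprocess(img, msk, size=size, mean=mean, std=std)
        xs.append(t)
        ys.append(m)
    return np.stack(xs), np.stack(ys)
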