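"""Image/mask pair handling: loading, splitting, augmentation.

Pairs live either on disk (``images/`` and ``masks/`` directories with
matching file stems, PNG or JPEG) or come from the synthetic generator in
:mod:`defifnet.synth`.  Masks are binarized at 127 when read from 8-bit
files.  The splitter reproduces the 7:2:1 protocol with the test partition
fixed at round(N/10) and the validation partition at round(2N/10), assigned
by a seeded shuffle.  Augmentations (rotation, flips, crop-and-restore, and
synthetic dark body-hair strokes) apply the identical geometric transform to
image and mask, resample the mask with nearest neighbour so it stays binary,
and never let the hair strokes touch the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import transform as sktf

MASK_THRESHOLD = 127


@dataclass
class SamplePair:
    """One RGB image with its aligned binary mask."""

    image: np.ndarray            # (H, W, 3) uint8
    mask: np.ndarray             # (H, W) values {0, 1}
    identifier: str = ""
    source: str = "disk"         # "disk" | "synthetic"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image/mask dimension mismatch: image {self.image.shape[:2]} "
                f"vs mask {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be strictly binary after loading")


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratio (default 7:2:1) and shuffle seed."""

    ratio: tuple[float, float, float] = (7.0, 2.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.ratio) < 0 or sum(self.ratio) <= 0:
            raise ValueError(f"invalid split ratio {self.ratio}")


@dataclass
class AugmentConfig:
    """Geometric + hair-noise augmentation parameters."""

    rotation_deg: float = 30.0
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    crop_fraction: tuple[float, float] = (0.8, 1.0)
    hair_strokes: tuple[int, int] = (0, 8)
    hair_thickness: tuple[int, int] = (1, 3)
    hair_darkness: tuple[int, int] = (20, 80)
    hair_curvature: float = 0.35
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_hflip, self.p_vflip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        lo, hi = self.crop_fraction
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop fractions must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_dataset(identifiers: list[str], spec: SplitSpec = SplitSpec()
                  ) -> tuple[list[str], list[str], list[str]]:
    """Disjoint, covering (train, val, test) partition by seeded shuffle.

    The test partition holds round(N * r_test / sum(r)) items, validation
    round(N * r_val / sum(r)) capped so training stays non-empty, training
    the remainder.  With the default 7:2:1 ratio this reproduces test sizes
    of round(N/10).
    """
    ids = list(identifiers)
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 identifiers to split, got {n}")
    if len(set(ids)) != n:
        raise ValueError("identifiers must be unique")
    total = sum(spec.ratio)
    n_test = int(np.floor(n * spec.ratio[2] / total + 0.5))
    n_val = int(np.floor(n * spec.ratio[1] / total + 0.5))
    n_val = min(n_val, n - n_test - 1)  # keep training non-empty
    order = np.random.default_rng(spec.seed).permutation(n)
    shuffled = [ids[i] for i in order]
    test = sorted(shuffled[:n_test])
    val = sorted(shuffled[n_test:n_test + n_val])
    train = sorted(shuffled[n_test + n_val:])
    return train, val, test


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_sample_pair(image_path, mask_path) -> SamplePair:
    """Read an image/mask pair from disk, binarizing the mask at 127."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(p)
    image = np.asarray(iio.imread(image_path))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    image = image[..., :3].astype(np.uint8)
    mask = np.asarray(iio.imread(mask_path))
    if mask.ndim == 3:
        warnings.warn(f"mask {mask_path.name} is not grayscale; converting",
                      stacklevel=2)
        mask = mask[..., :3].mean(axis=-1)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image/mask dimension mismatch: image {image.shape[:2]} vs "
            f"mask {mask.shape} ({image_path.name})")
    mask = (mask > MASK_THRESHOLD).astype(np.uint8)
    return SamplePair(image=image, mask=mask, identifier=image_path.stem,
                      source="disk")


def discover_pairs(root) -> list[tuple[Path, Path]]:
    """Match `images/<stem>.*` with `masks/<stem>.*` under `root`."""
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    masks = {p.stem: p for p in sorted(mask_dir.glob("*"))}
    pairs = []
    for img in sorted(img_dir.glob("*")):
        if img.stem in masks:
            pairs.append((img, masks[img.stem]))
    return pairs


def resize_pair(pair: SamplePair, size: tuple[int, int]) -> SamplePair:
    """Resize to (H, W): bilinear for the image, nearest for the mask."""
    H, W = size
    img = sktf.resize(pair.image, (H, W), order=1, preserve_range=True,
                      anti_aliasing=True).astype(np.uint8)
    mask = sktf.resize(pair.mask, (H, W), order=0, preserve_range=True,
                       anti_aliasing=False).astype(np.uint8)
    return SamplePair(img, mask, pair.identifier, pair.source)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def augment_pair(pair: SamplePair, cfg: AugmentConfig,
                 rng: np.random.Generator) -> SamplePair:
    """Random rotation, flips and crop-and-restore, identically on both maps."""
    img = pair.image.astype(float)
    mask = pair.mask
    H, W = mask.shape

    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    if angle:
        img = sktf.rotate(img, angle, order=1, mode="reflect",
                          preserve_range=True)
        mask = sktf.rotate(mask.astype(float), angle, order=0, mode="constant",
                           cval=0, preserve_range=True)
    if rng.random() < cfg.p_hflip:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < cfg.p_vflip:
        img, mask = img[::-1], mask[::-1]

    frac = rng.uniform(*cfg.crop_fraction)
    ch, cw = max(1, round(H * frac)), max(1, round(W * frac))
    if ch < H or cw < W:
        top = rng.integers(0, H - ch + 1)
        left = rng.integers(0, W - cw + 1)
        img = img[top:top + ch, left:left + cw]
        mask = mask[top:top + ch, left:left + cw]
        img = sktf.resize(img, (H, W), order=1, preserve_range=True)
        mask = sktf.resize(mask.astype(float), (H, W), order=0,
                           preserve_range=True)

    out_img = np.clip(img, 0, 255).astype(np.uint8)
    out_mask = (np.asarray(mask) > 0.5).astype(np.uint8)
    return SamplePair(out_img, out_mask, pair.identifier, pair.source)


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + (t ** 2) * p2


def draw_hair_strokes(image: np.ndarray, cfg: AugmentConfig,
                      rng: np.random.Generator, k: int | None = None
                      ) -> tuple[np.ndarray, int]:
    """Composite `k` dark quadratic-Bezier strokes; returns (image, pixels)."""
    H, W = image.shape[:2]
    if k is None:
        k = int(rng.integers(cfg.hair_strokes[0], cfg.hair_strokes[1] + 1))
    canvas = image.astype(float)
    stroke = np.zeros((H, W), dtype=bool)
    for _ in range(k):
        p0 = rng.uniform([0, 0], [H - 1, W - 1])
        p2 = rng.uniform([0, 0], [H - 1, W - 1])
        mid = (p0 + p2) / 2
        span = np.linalg.norm(p2 - p0)
        p1 = mid + rng.normal(0, cfg.hair_curvature * max(span, 1.0), size=2)
        npts = max(int(2 * span), 2)
        pts = np.round(_bezier_points(p0, p1, p2, npts)).astype(int)
        pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < H)
                  & (pts[:, 1] >= 0) & (pts[:, 1] < W)]
        if not len(pts):
            continue
        thick = int(rng.integers(cfg.hair_thickness[0], cfg.hair_thickness[1] + 1))
        single = np.zeros((H, W), dtype=bool)
        single[pts[:, 0], pts[:, 1]] = True
        if thick > 1:
            from scipy import ndimage
            single = ndimage.binary_dilation(single, iterations=thick - 1)
        darkness = rng.integers(cfg.hair_darkness[0], cfg.hair_darkness[1] + 1)
        canvas[single] = canvas[single] * 0.25 + float(darkness) * 0.75
        stroke |= single
    return np.clip(canvas, 0, 255).astype(np.uint8), int(stroke.sum())


def add_hair_noise(pair: SamplePair, cfg: AugmentConfig,
                   rng: np.random.Generator, k: int | None = None) -> SamplePair:
    """Dark curved strokes on the image only; the mask is untouched."""
    img, _ = draw_hair_strokes(pair.image, cfg, rng, k=k)
    return SamplePair(img, pair.mask.copy(), pair.identifier, pair.source)


def binarize_prediction(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities into a strict binary mask (>= convention)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(p) >= threshold).astype(np.uint8)
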