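"""Synthetic image/mask generator for the two task regimes.

Two modes emulate the qualitative structure of the benchmark data without
any download:

* ``lesion`` — a single large irregular lesion on textured skin-tone
  background: the mask is a star-convex polygon whose radius varies as
  ``r(theta) = r0 * (1 + sum_k a_k sin(k theta + phi_k))``, the image is a
  noisy skin-coloured field with a darker textured fill inside the mask,
  Gaussian blur, pixel noise and optional dark hair strokes.
* ``nuclei`` — many small bright blobs on a dark field: the mask is a union
  of randomly placed ellipses honouring a minimum centre separation via
  rejection sampling.

Every sample is a pure function of ``(seed, index)``, so datasets regenerate
bit-identically.  Generated trees round-trip through
:func:`defifnet.data.load_sample_pair`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .data import AugmentConfig, SamplePair, draw_hair_strokes


@dataclass
class SyntheticSpec:
    """Distributional parameters of the fixture generator."""

    mode: str = "lesion"                     # "lesion" | "nuclei"
    image_size: tuple[int, int] = (64, 64)
    count: int = 16
    seed: int = 0
    # lesion geometry / appearance
    center_jitter: float = 0.08              # fraction of min(H, W)
    mean_radius_frac: float = 0.28           # of min(H, W)
    irregularity: float = 0.25               # radial harmonic amplitude
    harmonics: int = 4
    skin_rgb: tuple[int, int, int] = (205, 160, 140)
    lesion_rgb: tuple[int, int, int] = (120, 75, 60)
    color_jitter: float = 18.0
    blur_sigma: float = 1.2
    noise_sigma: float = 6.0
    hair_prob: float = 0.5
    hair: AugmentConfig = field(default_factory=lambda: AugmentConfig(
        hair_strokes=(2, 6), hair_thickness=(1, 2)))
    # nuclei geometry / appearance
    blob_count: tuple[int, int] = (5, 15)
    blob_radius: tuple[float, float] = (3.0, 7.0)
    min_separation: float = 4.0
    field_rgb: tuple[int, int, int] = (18, 18, 24)
    blob_rgb: tuple[int, int, int] = (190, 200, 215)

    def __post_init__(self):
        if not 0.0 < self.mean_radius_frac < 0.5:
            raise ValueError("mean_radius_frac must lie in (0, 0.5)")
        if self.blob_radius[0] < 1.0:
            raise ValueError("blob radii must be at least 1 px")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _rng_for(spec: SyntheticSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, index]))


def _textured_field(rng, shape, base_rgb, jitter, smooth=6.0):
    H, W = shape
    tex = rng.normal(0.0, 1.0, size=(H, W))
    tex = ndimage.gaussian_filter(tex, smooth)
    tex = tex / (np.abs(tex).max() + 1e-9)
    img = np.empty((H, W, 3), dtype=float)
    for c in range(3):
        img[..., c] = base_rgb[c] + jitter * tex
    return img


def _lesion_mask(rng, spec: SyntheticSpec) -> np.ndarray:
    H, W = spec.image_size
    m = min(H, W)
    for _ in range(10):
        cy = H / 2 + rng.uniform(-1, 1) * spec.center_jitter * m
        cx = W / 2 + rng.uniform(-1, 1) * spec.center_jitter * m
        r0 = spec.mean_radius_frac * m
        amps = rng.uniform(0, spec.irregularity, size=spec.harmonics) \
            / np.arange(1, spec.harmonics + 1)
        phases = rng.uniform(0, 2 * np.pi, size=spec.harmonics)
        theta = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        r = r0 * (1 + sum(a * np.sin((k + 1) * theta + p)
                          for k, (a, p) in enumerate(zip(amps, phases))))
        if (r <= 1.0).any():       # degenerate: redraw with clipped amplitude
            spec_amp = 0.5 * amps
            r = r0 * (1 + sum(a * np.sin((k + 1) * theta + p)
                              for k, (a, p) in enumerate(zip(spec_amp, phases))))
            if (r <= 1.0).any():
                continue
        rr, cc = skdraw.polygon(cy + r * np.sin(theta), cx + r * np.cos(theta),
                                shape=(H, W))
        mask = np.zeros((H, W), dtype=np.uint8)
        mask[rr, cc] = 1
        if mask.any():
            return mask
    raise RuntimeError("failed to draw a non-degenerate lesion mask")


def generate_lesion_sample(spec: SyntheticSpec, index: int) -> SamplePair:
    """One lesion image/mask pair, deterministic in (spec.seed, index)."""
    rng = _rng_for(spec, index)
    H, W = spec.image_size
    mask = _lesion_mask(rng, spec)
    img = _textured_field(rng, (H, W), spec.skin_rgb, spec.color_jitter)
    lesion = _textured_field(rng, (H, W), spec.lesion_rgb, spec.color_jitter,
                             smooth=3.0)
    img[mask.astype(bool)] = lesion[mask.astype(bool)]
    img = ndimage.gaussian_filter(img, (spec.blur_sigma, spec.blur_sigma, 0))
    img = img + rng.normal(0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    if rng.random() < spec.hair_prob:
        img, _ = draw_hair_strokes(img, spec.hair, rng)
    return SamplePair(img, mask, f"lesion{index:04d}", source="synthetic")


def generate_nuclei_sample(spec: SyntheticSpec, index: int) -> SamplePair:
    """One nuclei image/mask pair, deterministic in (spec.seed, index)."""
    rng = _rng_for(spec, index)
    H, W = spec.image_size
    k = int(rng.integers(spec.blob_count[0], spec.blob_count[1] + 1))
    centers: list[np.ndarray] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < k and tries < 200 * k:
        tries += 1
        r = rng.uniform(*spec.blob_radius)
        c = rng.uniform([r + 1, r + 1], [H - r - 2, W - r - 2])
        if all(np.linalg.norm(c - c0) >= r + r0 + spec.min_separation
               for c0, r0 in zip(centers, radii)):
            centers.append(c)
            radii.append(r)
    if len(centers) < k:
        warnings.warn(f"placed only {len(centers)} of {k} blobs after "
                      "rejection-sampling retries", stacklevel=2)
    mask = np.zeros((H, W), dtype=np.uint8)
    for c, r in zip(centers, radii):
        ry, rx = r, r * rng.uniform(0.7, 1.0)
        rr, cc = skdraw.ellipse(c[0], c[1], ry, rx, shape=(H, W),
                                rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = 1
    img = _textured_field(rng, (H, W), spec.field_rgb, 6.0)
    blob = _textured_field(rng, (H, W), spec.blob_rgb, 10.0, smooth=2.0)
    img[mask.astype(bool)] = blob[mask.astype(bool)]
    img = ndimage.gaussian_filter(img, (0.8, 0.8, 0))
    img = img + rng.normal(0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return SamplePair(img, mask, f"nuclei{index:04d}", source="synthetic")


def generate_sample(spec: SyntheticSpec, index: int) -> SamplePair:
    if spec.mode == "lesion":
        return generate_lesion_sample(spec, index)
    if spec.mode == "nuclei":
        return generate_nuclei_sample(spec, index)
    raise ValueError(f"unknown mode {spec.mode!r}")


def generate_arrays(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """All samples as arrays: images (N, H, W, 3) uint8, masks (N, H, W)."""
    pairs = [generate_sample(spec, i) for i in range(spec.count)]
    return (np.stack([p.image for p in pairs]),
            np.stack([p.mask for p in pairs]))


def generate_dataset(spec: SyntheticSpec, out_dir) -> Path:
    """Write `images/` + `masks/` PNG trees and a manifest; returns its path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = ["identifier\tmode\tseed\tindex\tforeground_px"]
    for i in range(spec.count):
        pair = generate_sample(spec, i)
        iio.imwrite(out / "images" / f"{pair.identifier}.png", pair.image)
        iio.imwrite(out / "masks" / f"{pair.identifier}.png",
                    (pair.mask * 255).astype(np.uint8))
        rows.append(f"{pair.identifier}\t{spec.mode}\t{spec.seed}\t{i}\t"
                    f"{int(pair.mask.sum())}")
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
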