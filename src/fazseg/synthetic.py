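"""Synthetic OCTA-like en-face images with known FAZ ground truth.

Clinical OCTA en-face projections of the superficial vascular plexus
show a dark, roughly central avascular region (the FAZ) with an
irregular boundary, surrounded by bright curvilinear capillary texture,
and are degraded by salt-and-pepper noise, horizontal scan-line
artifacts, blur, and patches of capillary dropout.  This module emulates
those phenomena with simple, fully seeded mechanics so that every other
part of the package can be exercised against known ground truth:

* The FAZ is a star-convex polygon r(theta) = r0 (1 + sum_k a_k
  cos(k theta + phi_k)) with random phases, rasterized at a jittered
  centre; the continuous polygon provides analytic truth for area and
  perimeter.
* Vessels are persistent random-walk strokes clipped to zero inside the
  FAZ, over a low-intensity speckle background.
* Degradations are applied in a fixed order: capillary-dropout ellipses,
  salt-and-pepper flips, scan lines, Gaussian blur.

Default magnitudes follow the reported normal-eye FAZ morphometry on a
3 mm field (area mode near 0.275 mm^2, range roughly 0.06–0.5 mm^2).
Per-sample substreams come from a counter-based Philox generator keyed
by base_seed + index, so datasets are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.draw import ellipse as draw_ellipse

__all__ = ["SynthConfig", "SyntheticSample", "sample_faz_mask",
           "generate_vessels", "degrade", "make_dataset"]


@dataclass
class SynthConfig:
    height: int = 320
    width: int = 320
    field_mm: float = 3.0
    # FAZ geometry (pixels); None -> scaled from the image width in
    # __post_init__ to match the reported normal-eye morphometry
    radius_mean_px: Optional[float] = None
    radius_sd_px: Optional[float] = None
    radius_range_px: Optional[Tuple[float, float]] = None
    boundary_harmonics: int = 6
    boundary_roughness: float = 0.10     # sum of |a_k| scale
    center_jitter_px: Optional[float] = None
    # vessels
    vessel_walkers: int = 170
    vessel_intensity: Tuple[float, float] = (0.45, 1.0)
    background_speckle: float = 0.10
    # degradations
    salt_pepper_p: float = 0.015
    scan_line_count: int = 5
    scan_line_strength: float = 0.25
    blur_sigma: float = 0.8
    dropout_patches: int = 3
    dropout_size_px: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        w = self.width
        if self.radius_mean_px is None:
            # area mode ~0.275 mm^2 on a field_mm-wide image
            self.radius_mean_px = 0.0986 * w
        if self.radius_sd_px is None:
            self.radius_sd_px = 0.022 * w
        if self.radius_range_px is None:
            self.radius_range_px = (0.046 * w, 0.133 * w)
        if self.center_jitter_px is None:
            self.center_jitter_px = 0.04 * w
        if self.dropout_size_px is None:
            self.dropout_size_px = 0.055 * w
        lo, hi = self.radius_range_px
        if not (0 < lo <= hi < min(self.height, self.width) / 2):
            raise ValueError("radius range must be positive and fit the image")
        if not (0.0 <= self.salt_pepper_p <= 1.0):
            raise ValueError("salt_pepper_p must lie in [0, 1]")

    @property
    def mm_per_pixel(self) -> float:
        return self.field_mm / self.width

    def replace(self, **kw) -> "SynthConfig":
        d = asdict(self)
        d.update(kw)
        return SynthConfig(**d)

    @classmethod
    def clear(cls, **kw) -> "SynthConfig":
        """Low-artifact stratum mimicking visually clear scans."""
        base = dict(salt_pepper_p=0.004, scan_line_count=0,
                    scan_line_strength=0.0, blur_sigma=0.5,
                    dropout_patches=0, boundary_roughness=0.05)
        base.update(kw)
        return cls(**base)

    @classmethod
    def noisy(cls, **kw) -> "SynthConfig":
        """Heavily degraded stratum (dropout, scan lines, blur, noise)."""
        base = dict(salt_pepper_p=0.03, scan_line_count=9,
                    scan_line_strength=0.35, blur_sigma=1.3,
                    dropout_patches=6, boundary_roughness=0.10)
        base.update(kw)
        return cls(**base)


@dataclass
class SyntheticSample:
    image: np.ndarray                # (H, W, 3) float32 in [0, 1]
    gt_mask: np.ndarray              # (H, W) uint8
    true_area_mm2: float
    true_perimeter_mm: float
    params: dict = field(default_factory=dict)


def _shoelace(poly):
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def sample_faz_mask(cfg: SynthConfig, rng: np.random.Generator,
                    n_theta: int = 720):
    """Draw one FAZ shape; returns (mask uint8, polygon (n,2) row/col).

    The polygon is the continuous generating boundary, so shoelace area /
    polyline length on it give the analytic truth.
    """
    h, w = cfg.height, cfg.width
    lo, hi = cfg.radius_range_px
    for _ in range(20):
        r0 = float(np.clip(rng.normal(cfg.radius_mean_px, cfg.radius_sd_px),
                           lo, hi))
        k = np.arange(1, cfg.boundary_harmonics + 1)
        amp = cfg.boundary_roughness * rng.random(len(k)) / np.sqrt(k)
        phase = rng.uniform(0, 2 * np.pi, len(k))
        cy = h / 2 + rng.normal(0, cfg.center_jitter_px)
        cx = w / 2 + rng.normal(0, cfg.center_jitter_px)
        theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        r = r0 * (1.0 + (amp[None, :] * np.cos(
            k[None, :] * theta[:, None] + phase[None, :])).sum(axis=1))
        r = np.maximum(r, 0.2 * r0)
        rows = cy + r * np.sin(theta)
        cols = cx + r * np.cos(theta)
        if rows.min() < 2 or cols.min() < 2 or rows.max() > h - 3 \
                or cols.max() > w - 3:
            continue
        rr, cc = draw_polygon(rows, cols, shape=(h, w))
        mask = np.zeros((h, w), dtype=np.uint8)
        mask[rr, cc] = 1
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        if n != 1:
            continue
        poly = np.stack([rows, cols], axis=1)
        return mask, poly
    raise RuntimeError("could not place a FAZ polygon inside the image")


def generate_vessels(faz_mask: np.ndarray, cfg: SynthConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Bright curvilinear vessel strokes around the FAZ, zero inside it."""
    h, w = faz_mask.shape
    img = np.zeros((h, w), dtype=np.float32)
    n_steps = int(0.6 * max(h, w))
    for _ in range(cfg.vessel_walkers):
        # seeds: mostly at the FAZ border ring, some anywhere
        if rng.random() < 0.4:
            rows, cols = np.nonzero(faz_mask)
            if len(rows):
                j = rng.integers(len(rows))
                y, x = float(rows[j]), float(cols[j])
            else:
                y, x = rng.uniform(0, h), rng.uniform(0, w)
        else:
            y, x = rng.uniform(0, h), rng.uniform(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        inten = rng.uniform(*cfg.vessel_intensity)
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.35)
            y += np.sin(ang)
            x += np.cos(ang)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < h and 0 <= ix < w):
                break
            img[iy, ix] = max(img[iy, ix], inten)
            if rng.random() < 0.15 and 0 <= iy < h and 0 <= ix + 1 < w:
                img[iy, ix + 1] = max(img[iy, ix + 1], inten * 0.8)
    img = np.maximum(img, (cfg.background_speckle
                           * rng.random((h, w))).astype(np.float32))
    img[faz_mask > 0] = 0.0
    return np.clip(img, 0.0, 1.0)


def degrade(image: np.ndarray, cfg: SynthConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Apply capillary dropout, salt & pepper, scan lines, then blur."""
    img = np.array(image, dtype=np.float32, copy=True)
    h, w = img.shape[:2]
    for _ in range(cfg.dropout_patches):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = max(cfg.dropout_size_px * rng.uniform(0.5, 1.5), 1.5)
        rx = max(cfg.dropout_size_px * rng.uniform(0.5, 1.5), 1.5)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w),
                              rotation=rng.uniform(0, np.pi))
        img[rr, cc] *= rng.uniform(0.0, 0.25)
    if cfg.salt_pepper_p > 0:
        flip = rng.random((h, w)) < cfg.salt_pepper_p
        img[flip] = rng.integers(0, 2, size=int(flip.sum())).astype(np.float32)
    for _ in range(cfg.scan_line_count):
        row = rng.integers(0, h)
        thickness = int(rng.integers(1, 3))
        delta = cfg.scan_line_strength * rng.uniform(-1.0, 1.0)
        img[row:row + thickness, :] = np.clip(
            img[row:row + thickness, :] + delta, 0.0, 1.0)
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma)
    return np.clip(img, 0.0, 1.0)


def make_sample(cfg: SynthConfig, seed: int) -> SyntheticSample:
    """One image/mask pair from a counter-based substream keyed by seed."""
    rng = np.random.Generator(np.random.Philox(key=seed))
    mask, poly = sample_faz_mask(cfg, rng)
    vessels = generate_vessels(mask, cfg, rng)
    degraded = degrade(vessels, cfg, rng)
    image = np.repeat(degraded[:, :, None], 3, axis=2)
    s = cfg.mm_per_pixel
    closed = np.vstack([poly, poly[:1]])
    per_px = float(np.hypot(*np.diff(closed, axis=0).T).sum())
    return SyntheticSample(
        image=image.astype(np.float32), gt_mask=mask,
        true_area_mm2=float(_shoelace(poly) * s * s),
        true_perimeter_mm=per_px * s,
        params={"seed": seed, "mm_per_pixel": s,
                "salt_pepper_p": cfg.salt_pepper_p,
                "scan_line_count": cfg.scan_line_count,
                "blur_sigma": cfg.blur_sigma,
                "dropout_patches": cfg.dropout_patches})


def make_dataset(n: int, cfg: SynthConfig = None, base_seed: int = 0):
    """``n`` samples with per-sample seeds ``base_seed + i`` + a manifest."""
    import pandas as pd
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or SynthConfig()
    samples: List[SyntheticSample] = []
    rows = []
    for i in range(n):
        s = make_sample(cfg, base_seed + i)
        samples.append(s)
        rows.append({"index": i, "seed": base_seed + i,
                     "true_area_mm2": s.true_area_mm2,
                     "true_perimeter_mm": s.true_perimeter_mm,
                     **{k: v for k, v in s.params.items() if k != "seed"}})
    manifest = pd.DataFrame(rows)
    return samples, manifest


def dataset_arrays(samples):
    """Stack samples into (images, masks) arrays for the trainer."""
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.gt_mask for s in samples])
    return images, masks
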