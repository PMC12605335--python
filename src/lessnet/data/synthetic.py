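"""Synthetic endoscopy-like image/mask generator.

Real nasal-endoscopy frames of bleeding episodes show dark-red hemorrhage
regions on a textured pink mucosa, frequently confounded by specular
reflections from the light source and motion blur.  The generator emulates
exactly those ingredients — it makes no attempt at photorealism, only at
reproducing the structure a segmentation model must learn: a reddish
irregular foreground whose extent is controlled, distractors that are
*never* foreground, and a binary mask.

Lesion shapes follow the condition taxonomy of bleeding presentations:
``point`` (1-3 small foci), ``extensive`` (one large region),
``trapezoidal`` (a perspective-distorted quadrilateral patch) and
``vessel`` (a thin curved streak).  Each mask's foreground fraction is set
by quantile-thresholding a smooth scalar field, so the requested area
range is met exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

LESION_KINDS = ("point", "extensive", "trapezoidal", "vessel")


@dataclass
class ImageSample:
    """One RGB frame with an optional binary mask (0=background, 1=anomaly)."""

    id: str
    image: np.ndarray  # (H, W, 3) uint8
    mask: Optional[np.ndarray] = None  # (H, W) in {0, 1}

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be HxWx3")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError("mask and image spatial dimensions differ")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("mask may contain only values 0 and 1")
            self.mask = self.mask.astype(np.uint8)


@dataclass
class SyntheticConfig:
    image_size: int = 512
    lesion_kinds: Sequence[str] = LESION_KINDS
    lesion_area_fraction_range: tuple[float, float] = (0.01, 0.10)
    reflection_probability: float = 0.5
    blur_probability: float = 0.3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(
                f"lesion_area_fraction_range must satisfy 0 < lo <= hi < 1, got ({lo}, {hi})")
        unknown = set(self.lesion_kinds) - set(LESION_KINDS)
        if unknown:
            raise ValueError(f"unknown lesion kinds: {sorted(unknown)}")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma)
    f -= f.min()
    rng_span = f.max() - f.min()
    return f / rng_span if rng_span > 0 else f


def _lesion_field(kind: str, rng: np.random.Generator, size: int) -> np.ndarray:
    """A smooth scalar field whose upper level sets look like the lesion
    category; thresholded at a quantile to hit the target area exactly."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    if kind == "point":
        n_foci = rng.integers(1, 4)
        f = np.zeros((size, size))
        for _ in range(n_foci):
            cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
            s = rng.uniform(0.03, 0.08) * size
            f = np.maximum(f, np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
        f += 0.15 * _smooth_noise(rng, size, size * 0.04)
    elif kind == "extensive":
        cy, cx = rng.uniform(0.3 * size, 0.7 * size, size=2)
        sy = rng.uniform(0.15, 0.3) * size
        sx = rng.uniform(0.15, 0.3) * size
        f = np.exp(-((yy - cy) ** 2 / (2 * sy * sy) + (xx - cx) ** 2 / (2 * sx * sx)))
        f += 0.3 * _smooth_noise(rng, size, size * 0.06)
    elif kind == "trapezoidal":
        # signed distance to a randomly-warped quadrilateral
        cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
        ang = np.sort(rng.uniform(0, 2 * np.pi) + np.arange(4) * (np.pi / 2)
                      + rng.uniform(-0.4, 0.4, size=4))
        rad = rng.uniform(0.1, 0.3, size=4) * size
        pts = np.stack([cy + rad * np.sin(ang), cx + rad * np.cos(ang)], axis=1)
        inside = np.zeros((size, size), dtype=bool)
        from skimage.draw import polygon
        rr, cc = polygon(pts[:, 0], pts[:, 1], shape=(size, size))
        inside[rr, cc] = True
        d_in = ndimage.distance_transform_edt(inside)
        d_out = ndimage.distance_transform_edt(~inside)
        f = d_in - d_out
    else:  # vessel
        n_ctrl = 5
        t = np.linspace(0, 1, n_ctrl)
        cy = rng.uniform(0.15, 0.85, size=n_ctrl) * size
        cx = np.linspace(rng.uniform(0.1, 0.3), rng.uniform(0.7, 0.9), n_ctrl) * size
        tt = np.linspace(0, 1, 20 * size // 64)
        py = np.interp(tt, t, cy)
        px = np.interp(tt, t, cx)
        curve = np.zeros((size, size), dtype=bool)
        iy = np.clip(np.round(py).astype(int), 0, size - 1)
        ix = np.clip(np.round(px).astype(int), 0, size - 1)
        curve[iy, ix] = True
        f = -ndimage.distance_transform_edt(~curve)
    return f


def _threshold_to_count(field: np.ndarray, k: int) -> np.ndarray:
    """Binary mask keeping exactly the ``k`` largest field values."""
    npix = field.size
    k = max(1, min(int(k), npix - 1))
    flat = field.reshape(-1)
    idx = np.argpartition(flat, npix - k)[npix - k:]
    mask = np.zeros(npix, dtype=np.uint8)
    mask[idx] = 1
    return mask.reshape(field.shape)


def _render(rng: np.random.Generator, mask: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    size = config.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size
    # mucosa: pink-orange gradient with smooth texture and a mild vignette
    base_r = 0.72 + 0.1 * (yy - 0.5) + 0.12 * (_smooth_noise(rng, size, size * 0.08) - 0.5)
    base_g = 0.42 + 0.08 * (xx - 0.5) + 0.10 * (_smooth_noise(rng, size, size * 0.08) - 0.5)
    base_b = 0.38 + 0.08 * (_smooth_noise(rng, size, size * 0.1) - 0.5)
    img = np.stack([base_r, base_g, base_b], axis=-1)
    r2 = (yy - 0.5) ** 2 + (xx - 0.5) ** 2
    img *= (1.0 - 0.5 * r2)[..., None]
    # lesion: dark-red band, soft-edged alpha from the hard mask
    alpha = ndimage.gaussian_filter(mask.astype(np.float64), size * 0.004)
    alpha = np.clip(alpha * 1.5, 0, 1) * (0.75 + 0.25 * _smooth_noise(rng, size, size * 0.03))
    alpha = np.maximum(alpha, mask * 0.7)
    lesion_color = np.array([rng.uniform(0.45, 0.6),
                             rng.uniform(0.03, 0.10),
                             rng.uniform(0.05, 0.12)])
    img = img * (1 - alpha[..., None]) + lesion_color * alpha[..., None]
    # specular reflections: near-saturated patches, always background
    if rng.uniform() < config.reflection_probability:
        for _ in range(rng.integers(1, 4)):
            cy, cx = rng.uniform(0.1, 0.9, size=2) * size
            sy = rng.uniform(0.01, 0.04) * size
            sx = rng.uniform(0.01, 0.04) * size
            spot = np.exp(-((np.mgrid[0:size][:, None] - cy) ** 2 / (2 * sy ** 2)
                            + (np.mgrid[0:size][None, :] - cx) ** 2 / (2 * sx ** 2)))
            img = img * (1 - spot[..., None]) + np.array([0.98, 0.97, 0.95]) * spot[..., None]
    if rng.uniform() < config.blur_probability:
        sigma = rng.uniform(0.5, 2.0)
        img = ndimage.gaussian_filter(img, (sigma, sigma, 0))
    img += rng.normal(0, 0.015, size=img.shape)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def generate_sample(index: int, config: SyntheticConfig) -> ImageSample:
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(index)]))
    kind = config.lesion_kinds[rng.integers(0, len(config.lesion_kinds))]
    lo, hi = config.lesion_area_fraction_range
    fraction = rng.uniform(lo, hi)
    field = _lesion_field(kind, rng, config.image_size)
    npix = config.image_size ** 2
    # keep the pixel count inside [lo, hi] exactly, rounding never escaping it
    k = int(np.clip(round(fraction * npix),
                    np.ceil(lo * npix), np.floor(hi * npix)))
    mask = _threshold_to_count(field, k)
    image = _render(rng, mask, config)
    return ImageSample(id=f"syn_{config.seed}_{index:05d}", image=image, mask=mask)


def generate_dataset(n: int, config: SyntheticConfig) -> list[ImageSample]:
    """Generate ``n`` seeded samples; identical seeds give identical pixels."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return [generate_sample(i, config) for i in range(n)]
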