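"""Augmentation policies.

Two families serve different purposes:

* **View policies** for consistency training: a *weak* view (random
  horizontal flip, minor brightness/contrast changes) and a *strong* view
  (the weak transforms plus rotations up to 20 degrees and saturation/hue
  shifts).  These generate the (original, weak, strong) triple compared by
  the triplet consistency loss.
* **Offline expansion**: the dataset-level x5 enlargement (each image plus
  four independently transformed variants) drawing flips, rotations,
  scaling, panning and photometric changes.

All geometric operations are applied identically to image and mask; the
mask is resampled nearest-neighbour (stays binary) with background fill,
the image bilinearly with reflective fill.  Photometric operations never
touch the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktf
from skimage.color import hsv2rgb, rgb2hsv

from .data.synthetic import ImageSample


@dataclass
class AugmentationPolicy:
    strength: str = "weak"
    hflip_probability: float = 0.5
    brightness_delta: float = 0.1
    contrast_factor_range: tuple[float, float] = (0.9, 1.1)
    rotation_limit_deg: float = 0.0
    saturation_delta: float = 0.0
    hue_delta: float = 0.0

    def __post_init__(self):
        if self.strength == "weak" and (self.rotation_limit_deg or
                                        self.saturation_delta or self.hue_delta):
            raise ValueError("a weak policy must not rotate or shift saturation/hue")


WEAK_DEFAULT = AugmentationPolicy(strength="weak")
STRONG_DEFAULT = AugmentationPolicy(strength="strong", rotation_limit_deg=20.0,
                                    saturation_delta=0.2, hue_delta=0.05)


def sample_params(policy: AugmentationPolicy, rng: np.random.Generator) -> dict:
    lo, hi = policy.contrast_factor_range
    return {
        "hflip": bool(rng.uniform() < policy.hflip_probability),
        "brightness": float(rng.uniform(-policy.brightness_delta, policy.brightness_delta))
        if policy.brightness_delta else 0.0,
        "contrast": float(rng.uniform(lo, hi)) if (lo, hi) != (1.0, 1.0) else 1.0,
        "angle": float(rng.uniform(-policy.rotation_limit_deg, policy.rotation_limit_deg))
        if policy.rotation_limit_deg else 0.0,
        "saturation": float(rng.uniform(-policy.saturation_delta, policy.saturation_delta))
        if policy.saturation_delta else 0.0,
        "hue": float(rng.uniform(-policy.hue_delta, policy.hue_delta))
        if policy.hue_delta else 0.0,
    }


def _apply(sample: ImageSample, p: dict, new_id: str | None = None) -> ImageSample:
    img = sample.image.astype(np.float64) / 255.0
    mask = sample.mask
    if p.get("hflip"):
        img = img[:, ::-1]
        mask = mask[:, ::-1] if mask is not None else None
    if p.get("vflip"):
        img = img[::-1]
        mask = mask[::-1] if mask is not None else None
    tf = None
    if p.get("angle") or p.get("scale", 1.0) != 1.0 or p.get("shift_y") or p.get("shift_x"):
        h, w = img.shape[:2]
        centre = np.array([w, h]) / 2.0 - 0.5
        tf = (sktf.AffineTransform(translation=-centre)
              + sktf.AffineTransform(rotation=np.deg2rad(p.get("angle", 0.0)),
                                     scale=p.get("scale", 1.0))
              + sktf.AffineTransform(translation=centre
                                     + np.array([p.get("shift_x", 0.0) * w,
                                                 p.get("shift_y", 0.0) * h])))
    if tf is not None:
        img = sktf.warp(img, tf.inverse, order=1, mode="symmetric", preserve_range=True)
        if mask is not None:
            mask = sktf.warp(mask.astype(np.float64), tf.inverse, order=0,
                             mode="constant", cval=0.0, preserve_range=True)
            mask = (mask > 0.5).astype(np.uint8)
    if p.get("contrast", 1.0) != 1.0:
        img = (img - 0.5) * p["contrast"] + 0.5
    if p.get("brightness"):
        img = img + p["brightness"]
    if p.get("saturation") or p.get("hue"):
        hsv = rgb2hsv(np.clip(img, 0, 1))
        hsv[..., 0] = (hsv[..., 0] + p.get("hue", 0.0)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + p.get("saturation", 0.0), 0, 1)
        img = hsv2rgb(hsv)
    out = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    if mask is not None:
        mask = np.ascontiguousarray(mask)
    return ImageSample(id=new_id or sample.id, image=np.ascontiguousarray(out), mask=mask)


def weak_view(sample: ImageSample, seed: int,
              policy: AugmentationPolicy = WEAK_DEFAULT
              ) -> tuple[ImageSample, dict]:
    """Weak view plus the sampled parameters (needed to undo geometry)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x77]))
    p = sample_params(policy, rng)
    return _apply(sample, p), p


def strong_view(sample: ImageSample, seed: int,
                policy: AugmentationPolicy = STRONG_DEFAULT
                ) -> tuple[ImageSample, dict]:
    """Strong view plus the sampled parameters."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x55]))
    p = sample_params(policy, rng)
    return _apply(sample, p), p


def weak_augment(sample: ImageSample, seed: int,
                 policy: AugmentationPolicy = WEAK_DEFAULT) -> ImageSample:
    """The weak view generator t(.): flip + minor photometric jitter."""
    return weak_view(sample, seed, policy)[0]


def strong_augment(sample: ImageSample, seed: int,
                   policy: AugmentationPolicy = STRONG_DEFAULT) -> ImageSample:
    """The strong view generator T(.): weak transforms plus rotations up to
    the policy limit and saturation/hue shifts."""
    return strong_view(sample, seed, policy)[0]


def _offline_params(rng: np.random.Generator) -> dict:
    return {
        "hflip": bool(rng.uniform() < 0.5),
        "vflip": bool(rng.uniform() < 0.5),
        "angle": float(rng.uniform(-15.0, 15.0)),
        "scale": float(rng.uniform(0.9, 1.1)),
        "shift_y": float(rng.uniform(-0.1, 0.1)),
        "shift_x": float(rng.uniform(-0.1, 0.1)),
        "brightness": float(rng.uniform(-0.1, 0.1)),
        "contrast": float(rng.uniform(0.9, 1.1)),
    }


def expand_offline(samples: list[ImageSample], seed: int, factor: int = 5) -> list[ImageSample]:
    """Offline dataset expansion: each sample plus ``factor - 1`` variants,
    every variant one random composition of flips, rotation, scaling,
    panning and brightness/contrast changes."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out: list[ImageSample] = []
    for i, s in enumerate(samples):
        if s.mask is None:
            raise ValueError(f"sample {s.id} has no mask; offline expansion needs masks")
        out.append(s)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xAA, i]))
        for k in range(factor - 1):
            out.append(_apply(s, _offline_params(rng), new_id=f"{s.id}_aug{k + 1}"))
    return out
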