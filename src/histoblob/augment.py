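"""Seeded geometric augmentation for small histology image sets.

Each input image is expanded into the cartesian product of the configured
rotations, scales and shifts, plus optional flips and random crops.  All
warps keep the original frame size, reflect-pad out-of-frame pixels (black
borders would confound downstream thresholding) and use bilinear
interpolation; nearest-neighbor is used when a label mask is co-augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from skimage import transform as sktf

__all__ = ["AugmentConfig", "augment_image", "augment_dataset"]


@dataclass
class AugmentConfig:
    rotations: list[float] = field(default_factory=lambda: [0.0])
    scales: list[float] = field(default_factory=lambda: [1.0])
    shifts: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 0.0)])
    crops: int = 0
    crop_fraction: float = 0.8
    flip_horizontal: bool = False
    flip_vertical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("scale factors must be positive")
        if not (0 < self.crop_fraction <= 1):
            raise ValueError("crop_fraction must be in (0, 1]")
        if self.crops < 0:
            raise ValueError("crops must be non-negative")

    @property
    def multiplier(self) -> int:
        """Deterministic number of outputs per input image."""
        n = len(self.rotations) * len(self.scales) * len(self.shifts)
        n += int(self.flip_horizontal) + int(self.flip_vertical)
        n += self.crops
        return n


def _warp(img: np.ndarray, rot_deg: float, scale: float,
          shift_frac: tuple[float, float], order: int) -> np.ndarray:
    h, w = img.shape[:2]
    if rot_deg == 0 and scale == 1.0 and shift_frac == (0.0, 0.0):
        return img.copy()
    center = np.array([(w - 1) / 2, (h - 1) / 2])  # (x, y)
    shift_xy = np.array([shift_frac[1] * w, shift_frac[0] * h])
    tf = (
        sktf.AffineTransform(translation=-center)
        + sktf.AffineTransform(rotation=np.deg2rad(rot_deg), scale=scale)
        + sktf.AffineTransform(translation=center + shift_xy)
    )
    return sktf.warp(img, tf.inverse, mode="reflect", order=order, preserve_range=True)


def augment_image(img: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator | None = None,
                  order: int = 1) -> list[np.ndarray]:
    """All configured transforms of one image, frame size preserved.

    Output order: rotation x scale x shift products first, then flips, then
    random crops.  Deterministic given the config seed.
    """
    img = np.asarray(img, float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: list[np.ndarray] = []
    for rot, scale, shift in product(config.rotations, config.scales, config.shifts):
        out.append(_warp(img, rot, scale, shift, order))
    if config.flip_horizontal:
        out.append(img[:, ::-1].copy())
    if config.flip_vertical:
        out.append(img[::-1, :].copy())
    h, w = img.shape[:2]
    ch = max(1, int(round(config.crop_fraction * h)))
    cw = max(1, int(round(config.crop_fraction * w)))
    if ch > h or cw > w:
        raise ValueError("crop larger than image")
    for _ in range(config.crops):
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        crop = img[r0:r0 + ch, c0:c0 + cw]
        out.append(
            sktf.resize(crop, img.shape, order=order, mode="reflect",
                        preserve_range=True, anti_aliasing=False)
        )
    return out


def augment_dataset(images: list[np.ndarray], config: AugmentConfig,
                    order: int = 1) -> list[np.ndarray]:
    """Image-major concatenation of per-image augmentations.

    Output length is ``len(images) * config.multiplier``; a single seeded
    generator drives every random crop so the whole list is reproducible.
    """
    if len(images) == 0:
        raise ValueError("augment_dataset needs at least one image")
    rng = np.random.default_rng(config.seed)
    out: list[np.ndarray] = []
    for img in images:
        out.extend(augment_image(img, config, rng=rng, order=order))
    return out
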