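"""Image enhancement: thresholding, morphology and distance-transform
partitioning of the hematoxylin surface.

The stage input is the hematoxylin concentration channel (nuclei are the
bright structures on it).  Otsu or fixed thresholding produces a binary
nucleus mask; disk-structuring-element morphology cleans it; the Euclidean
distance transform then splits the frame into sure foreground (deep inside
nuclei), sure background (far from any nucleus) and the unknown rim between
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "RegionPartition",
    "binary_threshold",
    "morphology",
    "distance_transform",
    "partition_regions",
]


@dataclass
class RegionPartition:
    """Disjoint, exhaustive split of the frame.

    ``sure_fg``: pixels deep inside nuclei; ``sure_bg``: pixels far from any
    nucleus; ``unknown``: the rim in between.
    """

    sure_fg: np.ndarray
    sure_bg: np.ndarray
    unknown: np.ndarray


def binary_threshold(
    gray: np.ndarray, method: str = "otsu", level: float | None = None
) -> np.ndarray:
    """Foreground mask ``gray > t``; ``t`` from Otsu's criterion or fixed.

    Polarity: high values (hematoxylin-rich nuclei) are foreground.
    """
    gray = np.asarray(gray, float)
    if not np.all(np.isfinite(gray)):
        raise ValueError("gray image must be finite")
    if method == "otsu":
        if np.ptp(gray) == 0:
            raise ValueError("Otsu threshold undefined: degenerate single-bin histogram")
        t = threshold_otsu(gray)
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
        t = level
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return gray > t


_OPS = {"erode", "dilate", "open", "close", "clear_borders"}


def morphology(mask: np.ndarray, op: str, se_radius: int = 1) -> np.ndarray:
    """Binary morphology with a disk structuring element.

    ``open``/``close`` are the usual erosion-dilation compositions;
    ``clear_borders`` drops every 8-connected component touching the frame
    edge (the structuring element is unused there).
    """
    mask = np.asarray(mask, bool)
    if op not in _OPS:
        raise ValueError(f"unknown morphology op {op!r}")
    if op == "clear_borders":
        labels, _ = ndi.label(mask, structure=np.ones((3, 3), int))
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        border = border[border != 0]
        return mask & ~np.isin(labels, border)
    if se_radius < 1:
        raise ValueError("se_radius must be >= 1")
    se = disk(se_radius).astype(bool)

    # border convention: out-of-frame pixels are ignored (erosion treats them
    # as foreground, dilation as background), which preserves the duality
    # dilate(m) == ~erode(~m)
    def _erode(m):
        return ndi.binary_erosion(m, structure=se, border_value=1)

    def _dilate(m):
        return ndi.binary_dilation(m, structure=se, border_value=0)

    if op == "erode":
        return _erode(mask)
    if op == "dilate":
        return _dilate(mask)
    if op == "open":
        return _dilate(_erode(mask))
    return _erode(_dilate(mask))


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance from each foreground pixel to the nearest
    background pixel; exactly zero on the background."""
    return ndi.distance_transform_edt(np.asarray(mask, bool))


def partition_regions(
    mask: np.ndarray,
    dist: np.ndarray,
    fg_frac: float = 0.4,
    bg_dilate_radius: int = 3,
) -> RegionPartition:
    """Watershed-style marker partition from a mask and its distance map.

    sure foreground = distance above ``fg_frac`` of the global maximum;
    sure background = everything outside the mask dilated by
    ``bg_dilate_radius``; unknown = the remainder.  Returns three pairwise
    disjoint masks whose union covers the frame.
    """
    mask = np.asarray(mask, bool)
    dist = np.asarray(dist, float)
    if mask.shape != dist.shape:
        raise ValueError("mask and distance map shapes differ")
    dmax = dist.max()
    if dmax == 0:  # empty mask: everything is certain background
        sure_fg = np.zeros_like(mask)
    else:
        sure_fg = dist > fg_frac * dmax
    sure_bg = ~ndi.binary_dilation(mask, structure=disk(bg_dilate_radius).astype(bool))
    sure_bg &= ~sure_fg
    unknown = ~(sure_fg | sure_bg)
    return RegionPartition(sure_fg=sure_fg, sure_bg=sure_bg, unknown=unknown)
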