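"""Connected-components labeling and the Laplacian-of-Gaussian kernel.

The LoG kernel on the integer grid,

    LoG(x, y) = ((x^2 + y^2 - 2 sigma^2) / sigma^4) * exp(-(x^2 + y^2) / (2 sigma^2)),

responds strongly (negatively) at the center of bright blobs of scale
``sigma``.  Connected-components analysis groups thresholded foreground
pixels into labeled regions under 4- or 8-adjacency; small speckle
components are dropped and the survivors returned as individual binary
masks, largest first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "LoGKernel",
    "log_kernel",
    "log_response",
    "label_components",
    "component_masks",
]


@dataclass
class LoGKernel:
    sigma: float
    radius: int
    weights: np.ndarray  # (2*radius+1) x (2*radius+1)


def log_kernel(sigma: float, radius: int | None = None) -> LoGKernel:
    """Evaluate the LoG formula on the integer grid.

    The center weight is -2/sigma^2 and the kernel is point-symmetric.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = int(np.ceil(3 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    r2 = xx**2 + yy**2
    weights = (r2 - 2 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
    return LoGKernel(sigma=float(sigma), radius=radius, weights=weights)


def log_response(gray: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with the LoG kernel (reflect boundary).

    Sign convention follows the kernel: a bright blob on a dark background
    yields a negative response at its center.
    """
    kern = log_kernel(sigma)
    return ndi.convolve(np.asarray(gray, float), kern.weights, mode="reflect")


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label foreground components under 4- or 8-adjacency.

    Labels are contiguous 1..K, 0 is background.
    """
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], int)
    elif connectivity == 8:
        structure = np.ones((3, 3), int)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, _ = ndi.label(np.asarray(mask, bool), structure=structure)
    return labels


def component_masks(labels: np.ndarray, min_size: int = 20) -> list[np.ndarray]:
    """One binary mask per component of at least ``min_size`` pixels,
    ordered by descending size with ties broken by smaller label id."""
    labels = np.asarray(labels)
    k = labels.max()
    if k == 0:
        return []
    sizes = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    keep = [(int(sz), lab) for lab, sz in enumerate(sizes, start=1) if sz >= min_size]
    keep.sort(key=lambda t: (-t[0], t[1]))
    return [labels == lab for _, lab in keep]
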