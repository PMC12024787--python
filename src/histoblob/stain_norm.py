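"""Macenko stain estimation, unmixing, normalization and H/E separation.

Transmitted light through an H&E slide follows Beer-Lambert, so stain
absorbances add linearly in optical density, OD = -log10(I).  The Macenko
estimator recovers the two stain directions from an image alone: project the
tissue OD pixels onto the plane of their two leading singular vectors,
measure each pixel's angle in that plane, and take the extreme (alpha /
100-alpha percentile) angles as the hematoxylin and eosin unit vectors.
Per-pixel concentrations then come from non-negative least squares against
the 3x2 stain matrix, and normalization re-renders those concentrations
under a reference stain matrix.

Hematoxylin is identified as the extreme vector with the larger blue-to-red
OD ratio (nuclei absorb red light more than blue), which makes the H/E
assignment independent of the SVD's sign conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "MacenkoParams",
    "StainEstimationError",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "compute_concentrations",
    "normalize_to_reference",
    "separate_stains",
]


@dataclass
class MacenkoParams:
    """alpha: robust percentile for the extreme angles; beta: OD threshold
    below which pixels count as background/transparent and are discarded."""

    alpha: float = 1.0
    beta: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 50):
            raise ValueError("alpha must be in (0, 50)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


class StainEstimationError(ValueError):
    pass


def rgb_to_od(img: np.ndarray, i0: float = 1.0, eps: float | None = None) -> np.ndarray:
    """Optical density: od = -log10(max(img, eps) / i0).  The eps floor
    (default i0/255) keeps 8-bit black pixels finite."""
    if eps is None:
        eps = i0 / 255.0
    img = np.asarray(img, float)
    return -np.log10(np.maximum(img, eps) / i0)


def od_to_rgb(od: np.ndarray, i0: float = 1.0) -> np.ndarray:
    """Inverse transform, clipped to [0, 1]."""
    return np.clip(i0 * 10.0 ** (-np.asarray(od, float)), 0.0, 1.0)


def _extreme_vector(phi: float, basis: np.ndarray) -> np.ndarray:
    v = np.cos(phi) * basis[0] + np.sin(phi) * basis[1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    n = np.linalg.norm(v)
    if n == 0:
        raise StainEstimationError("degenerate extreme stain vector")
    return v / n


def estimate_stain_matrix(od: np.ndarray, params: MacenkoParams | None = None) -> np.ndarray:
    """Macenko stain-matrix estimate from an OD image (or N x 3 pixel list).

    Returns a 3x2 matrix with unit-norm, non-negative columns; column 0 is
    hematoxylin, column 1 eosin.
    """
    if params is None:
        params = MacenkoParams()
    pixels = np.asarray(od, float).reshape(-1, 3)
    tissue = pixels[np.all(pixels > params.beta, axis=1)]
    if tissue.shape[0] < 2:
        raise StainEstimationError(
            f"only {tissue.shape[0]} pixels exceed the OD threshold beta={params.beta}"
        )
    # plane of the two leading right-singular vectors
    _, s, vt = np.linalg.svd(tissue, full_matrices=False)
    if s[1] <= 1e-12 * s[0]:
        raise StainEstimationError("OD cloud has rank < 2; cannot separate two stains")
    basis = vt[:2]
    # orient so projections land in a consistent half-plane
    if basis[0].sum() < 0:
        basis = basis * np.array([[-1.0], [1.0]])
    proj = tissue @ basis.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, params.alpha)
    hi = np.percentile(phi, 100 - params.alpha)
    v1 = _extreme_vector(lo, basis)
    v2 = _extreme_vector(hi, basis)
    # blue-appearing hematoxylin absorbs red light far more than blue,
    # so its OD vector has the larger red-to-blue ratio; pink eosin is
    # the opposite (it mostly absorbs green)
    ratio1 = v1[0] / max(v1[2], 1e-12)
    ratio2 = v2[0] / max(v2[2], 1e-12)
    h, e = (v1, v2) if ratio1 > ratio2 else (v2, v1)
    return np.stack([h, e], axis=1)


def compute_concentrations(od: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Per-pixel non-negative least-squares stain concentrations.

    Solves conc = argmin_{c >= 0} ||M c - od||_2 for every pixel.  The
    unconstrained solution is used wherever it is already non-negative;
    only the violating pixels go through the active-set NNLS solver.
    """
    M = np.asarray(M, float)
    od_arr = np.asarray(od, float)
    shape = od_arr.shape[:-1]
    flat = od_arr.reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(M, flat.T, rcond=None)
    conc = conc.T
    bad = np.any(conc < 0, axis=1)
    if np.any(bad):
        idx = np.flatnonzero(bad)
        for i in idx:
            conc[i], _ = nnls(M, flat[i])
    conc = np.clip(conc, 0.0, None)
    return conc.reshape(*shape, 2)


def normalize_to_reference(
    img: np.ndarray,
    ref: np.ndarray,
    ref_maxC: np.ndarray,
    params: MacenkoParams | None = None,
) -> np.ndarray:
    """Re-render ``img`` under the reference stain matrix ``ref``.

    The source stain matrix and concentrations are estimated with Macenko;
    each concentration channel is scaled so that its 99th percentile matches
    ``ref_maxC``, then the image is re-rendered from the reference matrix.
    """
    od = rgb_to_od(img)
    M_src = estimate_stain_matrix(od, params)
    conc = compute_concentrations(od, M_src)
    ref_maxC = np.asarray(ref_maxC, float)
    src_max = np.percentile(conc.reshape(-1, 2), 99, axis=0)
    src_max = np.maximum(src_max, 1e-12)
    conc_scaled = conc * (ref_maxC / src_max)
    od_new = conc_scaled @ np.asarray(ref, float).T
    return od_to_rgb(od_new)


def separate_stains(img: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Render hematoxylin-only and eosin-only images.

    The returned pair partitions the stain signal in OD space:
    od(h_img) + od(e_img) = M @ C exactly (before any clipping).
    """
    M = np.asarray(M, float)
    conc = compute_concentrations(rgb_to_od(img), M)
    h_od = conc[..., :1] @ M[:, :1].T
    e_od = conc[..., 1:] @ M[:, 1:].T
    return od_to_rgb(h_od), od_to_rgb(e_od)
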