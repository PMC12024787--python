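"""Hessian blobness scoring and logistic false-positive elimination.

Each segmented candidate region T gets three features: the mean and maximum
of a per-pixel blobness score over its pixels, and its size N_T.  Blobness
at scale sigma is computed from the eigenvalues lambda1 <= lambda2 of the
scale-normalized (sigma^2) Gaussian Hessian: for a bright, locally convex
blob both eigenvalues are negative, and

    Blobness = sqrt(lambda1 * lambda2)   if lambda2 < 0, else 0

— a rotation-invariant score that vanishes on flat, dark or saddle-like
structure and is small on elongated ridges (one eigenvalue near zero).

A candidate-selection function maps the features to a retention probability:

    Z(T)  = beta0 + sum_i beta_i x_i
    Ls(T) = 1 / (1 + exp(-Z(T)))

with coefficients fitted by maximum likelihood (IRLS) on labeled candidates;
candidates with Ls below the cutoff (default 0.5, the sigmoid's natural
decision boundary) are discarded as false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import hessian_matrix, hessian_matrix_eigvals

__all__ = [
    "BlobCandidate",
    "SelectionModel",
    "Detection",
    "PerfectSeparationWarning",
    "hessian_blobness",
    "candidate_stats",
    "make_candidate",
    "fit_selection_model",
    "score_and_select",
]


@dataclass
class BlobCandidate:
    """A connected candidate region with its blobness statistics."""

    pixels: np.ndarray            # (N, 2) integer (row, col)
    blobness_mean: float
    blobness_max: float
    size: int
    z: float | None = None
    ls: float | None = None

    @property
    def features(self) -> np.ndarray:
        return np.array([self.blobness_mean, self.blobness_max, self.size], float)

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(self.pixels.mean(axis=0))


@dataclass
class SelectionModel:
    """Logistic selection coefficients on the standardized feature scale."""

    beta0: float
    betas: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    nf: int = 3

    def z_score(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.feature_means) / self.feature_sds
        return self.beta0 + x @ self.betas


@dataclass
class Detection:
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    mask: np.ndarray
    score: float


class PerfectSeparationWarning(UserWarning):
    pass


def hessian_blobness(surface: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized bright-blob score from Gaussian Hessian eigenvalues."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    H_elems = hessian_matrix(
        np.asarray(surface, float), sigma=sigma, order="rc",
        use_gaussian_derivatives=True, mode="reflect",
    )
    lam2, lam1 = hessian_matrix_eigvals(H_elems)  # returned in decreasing order
    lam1, lam2 = lam1 * sigma**2, lam2 * sigma**2  # lam1 <= lam2, scale-normalized
    blob = np.where(lam2 < 0, np.sqrt(np.clip(lam1 * lam2, 0, None)), 0.0)
    return blob


def candidate_stats(pixels: np.ndarray, blobness: np.ndarray) -> tuple[float, float, int]:
    """(mean, max, size) of the blobness values over a pixel set."""
    pixels = np.asarray(pixels, int)
    if pixels.size == 0:
        raise ValueError("candidate pixel set is empty")
    rows, cols = pixels[:, 0], pixels[:, 1]
    H, W = blobness.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= H or cols.max() >= W:
        raise ValueError("candidate pixels outside the frame")
    vals = blobness[rows, cols]
    return float(vals.mean()), float(vals.max()), int(len(vals))


def make_candidate(mask: np.ndarray, blobness: np.ndarray) -> BlobCandidate:
    """Build a BlobCandidate from a binary region mask."""
    pixels = np.argwhere(np.asarray(mask, bool))
    mean, mx, size = candidate_stats(pixels, blobness)
    return BlobCandidate(pixels=pixels, blobness_mean=mean, blobness_max=mx, size=size)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          tol: float = 1e-8, max_iter: int = 200) -> tuple[np.ndarray, bool]:
    """Newton/IRLS for logistic log-likelihood; X includes the intercept."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = _sigmoid(X @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        H = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
        grad = X.T @ (y - p) - ridge * beta
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def fit_selection_model(
    candidates: list[BlobCandidate] | np.ndarray,
    labels: np.ndarray,
) -> SelectionModel:
    """Maximum-likelihood logistic fit of true-vs-false candidate labels.

    Features are standardized internally (coefficients are reported on the
    standardized scale).  Perfectly separable data makes the unpenalized
    likelihood unbounded; in that case a warning is issued and a small ridge
    penalty regularizes the fit.
    """
    if isinstance(candidates, np.ndarray):
        X = np.asarray(candidates, float)
    else:
        X = np.array([c.features for c in candidates], float)
    y = np.asarray(labels, float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("candidates and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("selection-model fit needs both classes present")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("a feature is constant across all candidates")
    Xs = np.column_stack([np.ones(len(y)), (X - means) / sds])
    beta, converged = _irls(Xs, y)
    if not converged or np.max(np.abs(beta)) > 1e3:
        warnings.warn(
            "perfect separation detected; refitting with a ridge penalty",
            PerfectSeparationWarning,
            stacklevel=2,
        )
        beta, _ = _irls(Xs, y, ridge=1.0)
    return SelectionModel(
        beta0=float(beta[0]),
        betas=beta[1:],
        feature_means=means,
        feature_sds=sds,
        nf=X.shape[1],
    )


def score_and_select(
    candidates: list[BlobCandidate],
    model: SelectionModel,
    cutoff: float = 0.5,
    frame_shape: tuple[int, int] | None = None,
) -> list[Detection]:
    """Score every candidate with Ls and keep those with Ls >= cutoff,
    sorted by descending score."""
    if not candidates:
        return []
    X = np.array([c.features for c in candidates], float)
    z = model.z_score(X)
    ls = _sigmoid(z)
    detections = []
    for cand, zi, li in zip(candidates, z, ls):
        cand.z, cand.ls = float(zi), float(li)
        if li < cutoff:
            continue
        rows, cols = cand.pixels[:, 0], cand.pixels[:, 1]
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        if frame_shape is None:
            shape = (bbox[2], bbox[3])
        else:
            shape = frame_shape
        mask = np.zeros(shape, bool)
        mask[rows, cols] = True
        detections.append(
            Detection(centroid=cand.centroid, bbox=bbox, mask=mask, score=float(li))
        )
    detections.sort(key=lambda d: -d.score)
    return detections
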