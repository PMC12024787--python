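import numpy as np
import pytest

from histoblob import (
    PerfectSeparationWarning,
    SelectionModel,
    candidate_stats,
    fit_selection_model,
    hessian_blobness,
    make_candidate,
    score_and_select,
)
from histoblob.blobs import _sigmoid


def gaussian_blob(shape, cy, cx, sigma, amp=1.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


# ---------------------------------------------------------------------------
# blobness (Eqs. 5-6)
# ---------------------------------------------------------------------------

def test_blobness_peaks_at_blob_center():
    img = gaussian_blob((48, 48), 24, 24, 4.0)
    b = hessian_blobness(img, 4.0)
    assert b[24, 24] == b.max() > 0


def test_blobness_zero_on_flat():
    assert np.allclose(hessian_blobness(np.full((32, 32), 0.7), 2.0), 0.0)


def test_blobness_suppresses_ridge():
    img = np.zeros((48, 48))
    img[:, 22:26] = 1.0  # straight ridge: one curved direction only
    b = hessian_blobness(img, 3.0)
    blob = gaussian_blob((48, 48), 24, 24, 3.0)
    assert b[24, 24] < 0.3 * hessian_blobness(blob, 3.0)[24, 24]


def test_blobness_dark_blob_scores_zero():
    img = 1.0 - gaussian_blob((48, 48), 24, 24, 4.0)
    assert hessian_blobness(img, 4.0)[24, 24] == 0.0


def test_blobness_scale_invariance_of_normalized_response():
    """sigma^2-normalized response at matched scale is size-invariant."""
    b1 = hessian_blobness(gaussian_blob((64, 64), 32, 32, 3.0), 3.0)[32, 32]
    b2 = hessian_blobness(gaussian_blob((96, 96), 48, 48, 6.0), 6.0)[48, 48]
    assert abs(b1 - b2) / b1 < 0.05


def test_blobness_sigma_validation():
    with pytest.raises(ValueError):
        hessian_blobness(np.zeros((8, 8)), 0.0)


# ---------------------------------------------------------------------------
# candidate statistics
# ---------------------------------------------------------------------------

def test_candidate_stats_match_naive_resummation():
    rng = np.random.default_rng(0)
    blobness = rng.random((32, 32))
    pixels = np.argwhere(rng.random((32, 32)) > 0.8)
    mean, mx, size = candidate_stats(pixels, blobness)
    vals = [blobness[r, c] for r, c in pixels]  # naive loop
    assert abs(mean - sum(vals) / len(vals)) < 1e-12
    assert mx == max(vals)
    assert size == len(vals)


def test_candidate_stats_errors():
    with pytest.raises(ValueError):
        candidate_stats(np.empty((0, 2), int), np.zeros((8, 8)))
    with pytest.raises(ValueError):
        candidate_stats(np.array([[9, 0]]), np.zeros((8, 8)))


def test_make_candidate_roundtrip():
    mask = np.zeros((16, 16), bool)
    mask[4:8, 4:8] = True
    blobness = np.arange(256, dtype=float).reshape(16, 16)
    cand = make_candidate(mask, blobness)
    assert cand.size == 16
    assert cand.features.shape == (3,)
    assert np.allclose(cand.centroid, (5.5, 5.5))


# ---------------------------------------------------------------------------
# selection function (Eqs. 7-8)
# ---------------------------------------------------------------------------

def test_ls_of_zero_is_half_and_monotone():
    assert _sigmoid(np.array([0.0]))[0] == 0.5
    z = np.linspace(-20, 20, 201)
    s = _sigmoid(z)
    assert np.all(np.diff(s) > 0)
    assert np.all((s > 0) & (s < 1))


def test_model_z_score_formula():
    m = SelectionModel(
        beta0=0.5,
        betas=np.array([1.0, -2.0, 0.25]),
        feature_means=np.array([1.0, 2.0, 3.0]),
        feature_sds=np.array([2.0, 1.0, 4.0]),
    )
    x = np.array([3.0, 2.5, 7.0])
    want = 0.5 + 1.0 * (3 - 1) / 2 + (-2.0) * (2.5 - 2) / 1 + 0.25 * (7 - 3) / 4
    assert abs(m.z_score(x)[0] - want) < 1e-12


def test_fit_recovers_separation_direction():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(400, 3))
    y = _sigmoid(2.0 * X[:, 0] - 1.0 * X[:, 1]) > rng.random(400)
    m = fit_selection_model(X, y)
    assert m.betas[0] > 0 > m.betas[1]
    assert abs(m.betas[2]) < abs(m.betas[0])


def test_fit_matches_grid_search_oracle_tiny():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 1))
    y = (X[:, 0] + rng.normal(0, 1.5, 12)) > 0
    m = fit_selection_model(X, y)
    xs = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()

    def nll(b0, b1):
        z = b0 + b1 * xs
        return -(y * z - np.log1p(np.exp(z))).sum()

    b0g = b1g = 0.0
    half = 8.0
    for _ in range(12):
        b0s = np.linspace(b0g - half, b0g + half, 41)
        b1s = np.linspace(b1g - half, b1g + half, 41)
        vals = np.array([[nll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        b0g, b1g, half = b0s[i], b1s[j], half * 0.25
    assert abs(m.beta0 - b0g) < 1e-3
    assert abs(m.betas[0] - b1g) < 1e-3


def test_perfect_separation_warns_and_is_finite():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([False, False, True, True])
    with pytest.warns(PerfectSeparationWarning):
        m = fit_selection_model(X, y)
    assert np.isfinite(m.beta0) and np.all(np.isfinite(m.betas))


def test_null_labels_give_small_slopes():
    """Labels independent of features -> slopes near zero (no fake signal)."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(500, 3))
    y = rng.random(500) < 0.4
    m = fit_selection_model(X, y)
    assert np.all(np.abs(m.betas) < 0.3)


def test_fit_errors():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError):
        fit_selection_model(X, np.ones(10, bool))  # one class
    Xc = X.copy()
    Xc[:, 1] = 2.0
    with pytest.raises(ValueError):
        fit_selection_model(Xc, np.arange(10) % 2 == 0)  # constant feature
    with pytest.raises(ValueError):
        fit_selection_model(X, np.ones(7, bool))  # length mismatch


# ---------------------------------------------------------------------------
# score_and_select
# ---------------------------------------------------------------------------

def _toy_candidates():
    blobness = np.zeros((20, 20))
    blobness[5, 5], blobness[15, 15] = 0.9, 0.1
    out = []
    for r in (5, 15):
        mask = np.zeros((20, 20), bool)
        mask[r - 1 : r + 2, r - 1 : r + 2] = True
        out.append(make_candidate(mask, blobness))
    return out


def test_score_and_select_cutoff_and_order():
    cands = _toy_candidates()
    m = SelectionModel(
        beta0=0.0,
        betas=np.array([5.0, 0.0, 0.0]),
        feature_means=np.array([0.05, 0.0, 9.0]),
        feature_sds=np.array([0.05, 1.0, 1.0]),
    )
    dets = score_and_select(cands, m, cutoff=0.5, frame_shape=(20, 20))
    assert len(dets) == 1
    assert dets[0].score >= 0.5
    assert np.allclose(dets[0].centroid, (5.0, 5.0))
    # every candidate got scored in place
    assert all(c.ls is not None and c.z is not None for c in cands)
    # detections sorted by descending score
    all_dets = score_and_select(cands, m, cutoff=0.0, frame_shape=(20, 20))
    scores = [d.score for d in all_dets]
    assert scores == sorted(scores, reverse=True)


def test_score_and_select_empty():
    m = SelectionModel(
        beta0=0.0, betas=np.zeros(3),
        feature_means=np.zeros(3), feature_sds=np.ones(3),
    )
    assert score_and_select([], m) == []
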