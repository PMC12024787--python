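import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.morphology import disk

from histoblob import (
    binary_threshold,
    distance_transform,
    morphology,
    partition_regions,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def otsu_oracle(gray, n_bins=256):
    """Exhaustive between-class-variance search over every histogram split.

    Otsu's criterion is defined on the binned data: the threshold is the bin
    center whose split maximizes w0*w1*(mu0-mu1)^2.
    """
    counts, edges = np.histogram(np.asarray(gray, float).ravel(), bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = centers[0], -1.0
    for k in range(1, n_bins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]
    return best_t


def sliding_erode_oracle(mask, se):
    """Erosion = windowed min: output true iff every se-covered in-frame
    pixel is true (out-of-frame treated as true)."""
    r = se.shape[0] // 2
    H, W = mask.shape
    out = np.zeros_like(mask, bool)
    offs = np.argwhere(se) - r
    for i in range(H):
        for j in range(W):
            ok = True
            for di, dj in offs:
                ii, jj = i + di, j + dj
                if 0 <= ii < H and 0 <= jj < W and not mask[ii, jj]:
                    ok = False
                    break
            out[i, j] = ok
    return out


def sliding_dilate_oracle(mask, se):
    r = se.shape[0] // 2
    H, W = mask.shape
    out = np.zeros_like(mask, bool)
    offs = np.argwhere(se) - r
    for i in range(H):
        for j in range(W):
            hit = False
            for di, dj in offs:
                ii, jj = i + di, j + dj
                if 0 <= ii < H and 0 <= jj < W and mask[ii, jj]:
                    hit = True
                    break
            out[i, j] = hit
    return out


def edt_oracle(mask):
    """All-pairs brute-force Euclidean distance to the nearest background."""
    mask = np.asarray(mask, bool)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, float)
    for i, j in np.argwhere(mask):
        if len(bg) == 0:
            out[i, j] = np.inf
        else:
            out[i, j] = np.sqrt(((bg - (i, j)) ** 2).sum(axis=1).min())
    return out


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def test_otsu_bimodal():
    rng = np.random.default_rng(0)
    gray = np.concatenate([rng.normal(0.2, 0.03, 500), rng.normal(0.8, 0.03, 500)])
    mask = binary_threshold(gray.reshape(25, 40))
    assert 450 <= mask.sum() <= 550  # splits at the valley


def test_otsu_matches_exhaustive_oracle():
    for seed in range(5):
        gray = np.random.default_rng(seed).uniform(0, 1, (24, 24))
        t_oracle = otsu_oracle(gray)
        mask = binary_threshold(gray)
        assert np.array_equal(mask, gray > t_oracle)


def test_fixed_threshold():
    gray = np.linspace(0, 1, 16).reshape(4, 4)
    mask = binary_threshold(gray, method="fixed", level=0.5)
    assert np.array_equal(mask, gray > 0.5)


def test_threshold_errors():
    with pytest.raises(ValueError):
        binary_threshold(np.zeros((4, 4)))  # degenerate histogram
    with pytest.raises(ValueError):
        binary_threshold(np.eye(4), method="fixed")  # missing level
    with pytest.raises(ValueError):
        binary_threshold(np.full((4, 4), np.nan))
    with pytest.raises(ValueError):
        binary_threshold(np.eye(4), method="bogus")


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(4))
@pytest.mark.parametrize("radius", [1, 2])
def test_erode_dilate_match_sliding_oracles(seed, radius):
    mask = np.random.default_rng(seed).random((20, 20)) > 0.5
    se = disk(radius).astype(bool)
    assert np.array_equal(morphology(mask, "erode", radius), sliding_erode_oracle(mask, se))
    assert np.array_equal(morphology(mask, "dilate", radius), sliding_dilate_oracle(mask, se))


def test_open_close_compositions():
    mask = np.random.default_rng(3).random((24, 24)) > 0.4
    assert np.array_equal(
        morphology(mask, "open"), morphology(morphology(mask, "erode"), "dilate")
    )
    assert np.array_equal(
        morphology(mask, "close"), morphology(morphology(mask, "dilate"), "erode")
    )


@given(hnp.arrays(bool, (15, 15)), st.integers(1, 2))
@settings(max_examples=30, deadline=None)
def test_erode_dilate_duality(mask, radius):
    assert np.array_equal(
        morphology(mask, "dilate", radius), ~morphology(~mask, "erode", radius)
    )


def test_opening_removes_speckle_keeps_blob():
    mask = np.zeros((32, 32), bool)
    mask[5, 5] = True                      # isolated pixel
    mask[10:20, 10:20] = True              # solid blob
    opened = morphology(mask, "open", 1)
    assert not opened[5, 5]
    assert opened[12:18, 12:18].all()


def test_clear_borders():
    mask = np.zeros((16, 16), bool)
    mask[0:4, 0:4] = True      # touches frame
    mask[8:12, 8:12] = True    # interior
    out = morphology(mask, "clear_borders")
    assert not out[0:4, 0:4].any()
    assert out[8:12, 8:12].all()


def test_morphology_errors():
    with pytest.raises(ValueError):
        morphology(np.zeros((4, 4), bool), "blur")
    with pytest.raises(ValueError):
        morphology(np.zeros((4, 4), bool), "erode", se_radius=0)


# ---------------------------------------------------------------------------
# distance transform / partition
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_edt_matches_brute_force(seed):
    mask = np.random.default_rng(seed).random((16, 16)) > 0.4
    mask[0, 0] = False  # keep at least one background pixel
    assert np.allclose(distance_transform(mask), edt_oracle(mask))


def test_edt_zero_on_background():
    mask = np.zeros((8, 8), bool)
    mask[3:5, 3:5] = True
    d = distance_transform(mask)
    assert np.all(d[~mask] == 0) and np.all(d[mask] > 0)


def test_partition_disjoint_exhaustive():
    mask = np.zeros((32, 32), bool)
    mask[8:24, 8:24] = True
    part = partition_regions(mask, distance_transform(mask))
    total = (
        part.sure_fg.astype(int) + part.sure_bg.astype(int) + part.unknown.astype(int)
    )
    assert np.all(total == 1)  # pairwise disjoint and covering
    assert part.sure_fg.any() and part.sure_bg.any() and part.unknown.any()
    assert np.all(mask[part.sure_fg])          # sure fg inside the mask
    assert not np.any(mask[part.sure_bg])      # sure bg outside the mask


def test_partition_empty_mask():
    mask = np.zeros((8, 8), bool)
    part = partition_regions(mask, distance_transform(mask))
    assert not part.sure_fg.any()
    assert part.sure_bg.all()


def test_partition_shape_mismatch():
    with pytest.raises(ValueError):
        partition_regions(np.zeros((4, 4), bool), np.zeros((5, 5)))
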