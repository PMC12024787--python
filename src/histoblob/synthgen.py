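"""Seeded synthetic H&E scene generator.

Renders fields of elliptical, hematoxylin-rich nuclei on an eosin-stained
tissue background through the Beer-Lambert forward model

    I = I0 * 10**(-(M @ C))        (per pixel, per channel)

where ``M`` is a known 3x2 stain matrix (columns: hematoxylin, eosin unit OD
vectors) and ``C`` the per-pixel stain concentrations.  Because the scene
carries its own stain matrix, nucleus geometry and per-nucleus labels, every
downstream stage (stain estimation, enhancement, segmentation, blob scoring,
detection) can be tested against exact ground truth without any external
image data.

Noise is added in optical-density space so the linear unmixing model stays
exact: an OD perturbation of standard deviation ``noise_sd`` corresponds to
the residual the Macenko estimator actually has to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_STAIN_MATRIX",
    "Nucleus",
    "EosinPatch",
    "SyntheticScene",
    "PlacementError",
    "make_scene",
    "render_rgb",
    "concentration_fields",
    "ground_truth",
]

# Standard H&E absorbance directions (unit OD vectors, RGB order).
_H_DIR = np.array([0.65, 0.70, 0.29])
_E_DIR = np.array([0.07, 0.99, 0.11])
DEFAULT_STAIN_MATRIX = np.stack(
    [_H_DIR / np.linalg.norm(_H_DIR), _E_DIR / np.linalg.norm(_E_DIR)], axis=1
)


class PlacementError(ValueError):
    """Raised when nuclei cannot be placed inside the requested frame."""


@dataclass
class Nucleus:
    """An elliptical nucleus: center (row, col), semi-axes a >= b, angle in
    radians, hematoxylin concentration (OD units) and lesion flag."""

    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float
    h_conc: float
    is_lesion: bool = False
    # index of the nucleus this one was deliberately placed to overlap, if any
    anchor: int | None = None

    def __post_init__(self) -> None:
        a, b = self.axes
        if not (a >= b > 0):
            raise ValueError(f"semi-axes must satisfy a >= b > 0, got {self.axes}")
        if self.h_conc <= 0:
            raise ValueError("h_conc must be positive")

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Boolean mask of the ellipse interior, vectorized over coordinates."""
        a, b = self.axes
        dr = np.asarray(rows, float) - self.center[0]
        dc = np.asarray(cols, float) - self.center[1]
        c, s = np.cos(self.angle), np.sin(self.angle)
        # rotate into the ellipse frame (major axis along +col)
        u = dc * c + dr * s
        v = -dc * s + dr * c
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass
class EosinPatch:
    """A densely eosinophilic region (erythrocyte cluster / dense stroma):
    an ellipse carrying a high eosin concentration and no hematoxylin."""

    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float
    e_conc: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return Nucleus.contains(self, rows, cols)  # same ellipse geometry


@dataclass
class SyntheticScene:
    image_size: tuple[int, int]
    nuclei: list[Nucleus]
    stain_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_MATRIX.copy())
    e_background: float = 0.25
    h_background: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0
    clutter: list[Nucleus] = field(default_factory=list)
    eosin_patches: list[EosinPatch] = field(default_factory=list)


def _ellipses_intersect(n1: Nucleus, n2: Nucleus, shape: tuple[int, int]) -> bool:
    """Pixel-grid intersection test over the union bounding box."""
    r0 = int(max(0, min(n1.center[0] - n1.axes[0], n2.center[0] - n2.axes[0]) - 1))
    r1 = int(min(shape[0], max(n1.center[0] + n1.axes[0], n2.center[0] + n2.axes[0]) + 2))
    c0 = int(max(0, min(n1.center[1] - n1.axes[0], n2.center[1] - n2.axes[0]) - 1))
    c1 = int(min(shape[1], max(n1.center[1] + n1.axes[0], n2.center[1] + n2.axes[0]) + 2))
    if r1 <= r0 or c1 <= c0:
        return False
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return bool(np.any(n1.contains(rr, cc) & n2.contains(rr, cc)))


def _sample_axes(rng: np.random.Generator, lesion: bool) -> tuple[float, float]:
    if lesion:
        a = rng.uniform(8.0, 12.0)
        b = rng.uniform(0.7, 0.95) * a
    else:
        a = rng.uniform(5.0, 8.0)
        b = rng.uniform(0.6, 0.9) * a
    return a, b


def _sample_h_conc(rng: np.random.Generator, lesion: bool) -> float:
    # lesions are strictly darker (higher hematoxylin uptake)
    return rng.uniform(1.0, 1.4) if lesion else rng.uniform(0.45, 0.75)


def make_scene(
    n_nuclei: int,
    image_size: tuple[int, int] = (128, 128),
    overlap_fraction: float = 0.0,
    lesion_fraction: float = 0.0,
    seed: int = 0,
    *,
    n_clutter: int = 0,
    n_eosin_patches: int = 3,
    noise_sd: float = 0.0,
    e_background: float = 0.25,
    h_background: float = 0.05,
    stain_matrix: np.ndarray | None = None,
    max_tries: int = 2000,
) -> SyntheticScene:
    """Place ``n_nuclei`` elliptical nuclei in an ``image_size`` frame.

    Roughly ``overlap_fraction`` of the nuclei are placed so that their
    ellipse genuinely intersects an earlier (anchor) nucleus, with the center
    within one anchor semi-major axis; the rest are placed disjoint from all
    previous nuclei.  ``lesion_fraction`` of the nuclei are marked as lesions
    (larger and more hematoxylin-dense).  Centers are never inside another
    nucleus's ellipse, so every nucleus keeps its own center pixel in the
    ground-truth label image.

    ``n_clutter`` adds elongated fiber-like structures (high aspect ratio,
    moderate hematoxylin) that are rendered into the image but carry no
    ground-truth label — distractors for the blob-selection stage.
    ``n_eosin_patches`` adds densely eosinophilic ellipses (erythrocyte
    clusters) so the scene contains near-pure eosin pixels dense enough to
    survive the Macenko OD threshold.
    """
    H, W = image_size
    if H < 32 or W < 32:
        raise PlacementError(f"image_size must be at least 32x32, got {image_size}")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be non-negative")
    rng = np.random.default_rng(seed)
    M = DEFAULT_STAIN_MATRIX.copy() if stain_matrix is None else np.asarray(stain_matrix, float)

    n_lesion = int(round(lesion_fraction * n_nuclei))
    lesion_flags = np.zeros(n_nuclei, dtype=bool)
    lesion_flags[:n_lesion] = True
    rng.shuffle(lesion_flags)

    n_overlap = int(round(overlap_fraction * n_nuclei))
    overlap_flags = np.zeros(n_nuclei, dtype=bool)
    if n_nuclei > 1:
        # the first nucleus has nothing to overlap with
        idx = rng.choice(np.arange(1, n_nuclei), size=min(n_overlap, n_nuclei - 1), replace=False)
        overlap_flags[idx] = True

    nuclei: list[Nucleus] = []
    for i in range(n_nuclei):
        lesion = bool(lesion_flags[i])
        axes = _sample_axes(rng, lesion)
        h_conc = _sample_h_conc(rng, lesion)
        a = axes[0]
        if a + 1 >= min(H, W) / 2:
            raise PlacementError(
                f"image {image_size} too small for a nucleus of semi-axis {a:.1f}"
            )
        placed = False
        for _ in range(max_tries):
            angle = rng.uniform(0, np.pi)
            if overlap_flags[i] and nuclei:
                anchor_idx = int(rng.integers(len(nuclei)))
                anchor = nuclei[anchor_idx]
                theta = rng.uniform(0, 2 * np.pi)
                # offset in units of the larger semi-major axis, so a large
                # nucleus can still overlap a small anchor with both centers
                # outside the other's ellipse
                d = rng.uniform(0.5, 1.0) * max(anchor.axes[0], a)
                center = (
                    anchor.center[0] + d * np.sin(theta),
                    anchor.center[1] + d * np.cos(theta),
                )
            else:
                anchor_idx = None
                center = (rng.uniform(a + 1, H - a - 1), rng.uniform(a + 1, W - a - 1))
            if not (a + 1 <= center[0] <= H - a - 1 and a + 1 <= center[1] <= W - a - 1):
                continue
            cand = Nucleus(center, axes, angle, h_conc, lesion, anchor_idx)
            # center pixels (rounded to the grid) must stay outside every
            # other ellipse, in both directions, so each nucleus keeps its
            # own center pixel in the rendered label image
            rc = (round(center[0]), round(center[1]))
            if any(
                other.contains(rc[0], rc[1])
                or cand.contains(round(other.center[0]), round(other.center[1]))
                for other in nuclei
            ):
                continue
            if overlap_flags[i]:
                if not _ellipses_intersect(cand, nuclei[anchor_idx], image_size):
                    continue
            else:
                if any(_ellipses_intersect(cand, o, image_size) for o in nuclei):
                    continue
            nuclei.append(cand)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i} in image {image_size} after "
                f"{max_tries} tries (frame too crowded or too small)"
            )

    clutter: list[Nucleus] = []
    for _ in range(n_clutter):
        a = rng.uniform(12.0, 18.0)
        b = rng.uniform(1.2, 2.0)
        for _ in range(max_tries):
            center = (rng.uniform(a + 1, H - a - 1), rng.uniform(a + 1, W - a - 1))
            cand = Nucleus(center, (a, b), rng.uniform(0, np.pi), rng.uniform(0.5, 0.8))
            if not any(_ellipses_intersect(cand, n, image_size) for n in nuclei):
                clutter.append(cand)
                break

    patches: list[EosinPatch] = []
    occupied = nuclei + clutter
    for _ in range(n_eosin_patches):
        a = rng.uniform(6.0, 10.0)
        b = rng.uniform(0.6, 0.9) * a
        for _ in range(max_tries):
            center = (rng.uniform(a + 1, H - a - 1), rng.uniform(a + 1, W - a - 1))
            probe = Nucleus(center, (a, b), rng.uniform(0, np.pi), 1.0)
            if not any(_ellipses_intersect(probe, n, image_size) for n in occupied):
                # eosin dense enough that every OD channel clears beta=0.15
                patches.append(EosinPatch(center, (a, b), probe.angle, rng.uniform(2.15, 2.25)))
                break

    return SyntheticScene(
        image_size=image_size,
        nuclei=nuclei,
        stain_matrix=M,
        e_background=e_background,
        h_background=h_background,
        noise_sd=noise_sd,
        seed=seed,
        clutter=clutter,
        eosin_patches=patches,
    )


def concentration_fields(scene: SyntheticScene) -> np.ndarray:
    """Ground-truth H x W x 2 concentration map (hematoxylin, eosin).

    Inside a nucleus the hematoxylin concentration is the nucleus's own
    ``h_conc``; where nuclei overlap, the higher concentration wins.  Nuclei
    and clutter displace the eosin-stained cytoplasm, so eosin is zero inside
    them; eosin patches override the background eosin level.
    """
    H, W = scene.image_size
    rr, cc = np.mgrid[0:H, 0:W]
    h = np.full((H, W), scene.h_background, float)
    e = np.full((H, W), scene.e_background, float)
    for nuc in list(scene.nuclei) + list(scene.clutter):
        inside = nuc.contains(rr, cc)
        h[inside] = np.maximum(h[inside], nuc.h_conc)
        e[inside] = 0.0
    for patch in scene.eosin_patches:
        inside = patch.contains(rr, cc)
        e[inside] = patch.e_conc
        h[inside] = 0.0
    return np.stack([h, e], axis=-1)


def render_rgb(scene: SyntheticScene) -> np.ndarray:
    """Render the scene to an RGB image in [0, 1] via Beer-Lambert."""
    conc = concentration_fields(scene)
    od = conc @ scene.stain_matrix.T  # H x W x 3
    if scene.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0x0D]))
        od = np.clip(od + rng.normal(0.0, scene.noise_sd, od.shape), 0.0, None)
    return np.clip(10.0 ** (-od), 0.0, 1.0)


def ground_truth(scene: SyntheticScene) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Per-nucleus label image and the list of lesion centroids.

    Label ``k`` (1-based) covers the pixels of ``scene.nuclei[k-1]``; where
    two nuclei overlap, the one with the higher hematoxylin concentration
    claims the pixel.  Clutter is never labeled.
    """
    H, W = scene.image_size
    rr, cc = np.mgrid[0:H, 0:W]
    labels = np.zeros((H, W), dtype=np.int32)
    best = np.zeros((H, W), float)
    for k, nuc in enumerate(scene.nuclei, start=1):
        inside = nuc.contains(rr, cc)
        claim = inside & (nuc.h_conc > best)
        labels[claim] = k
        best[claim] = nuc.h_conc
    centroids = [n.center for n in scene.nuclei if n.is_lesion]
    return labels, centroids
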