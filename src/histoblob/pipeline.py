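"""End-to-end pipeline: stain separation -> enhancement -> connected
components -> active-contour refinement -> blob scoring -> selection ->
(optional) dense-network classification -> evaluation.

Each image is reduced to a list of blob candidates: the hematoxylin
concentration surface is thresholded and cleaned, connected components
become coarse nucleus masks, each mask is refined by a geodesic active
contour locked to the hematoxylin edges, and every refined region is scored
with Hessian blobness statistics.  A fitted logistic selection model then
discards false-positive candidates; what survives is reported as detections
and, when ground truth is available, scored by centroid matching.

The stage outputs form a funnel: detections are a subset of candidates.
Candidates come from connected components, but seeded contour refinement
may split one merged component into several candidates, so their count can
exceed the raw component count.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage as ndi

from . import blobs as blobs_mod
from . import components as comp_mod
from . import contours as cont_mod
from . import enhance as enh_mod
from . import stain_norm as stain_mod
from .augment import AugmentConfig
from .detectnet import EvalReport, NetConfig, evaluate_detections
from .synthgen import ground_truth, render_rgb

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "process_image",
           "fit_pipeline_selection_model"]

logger = logging.getLogger("histoblob")


@dataclass
class StainConfig:
    alpha: float = 1.0
    beta: float = 0.15


@dataclass
class EnhanceConfig:
    threshold_method: str = "otsu"
    threshold_level: float | None = None
    morphology_sequence: list[tuple[str, int]] = field(default_factory=lambda: [("open", 1)])
    fg_frac: float = 0.4
    bg_dilate_radius: int = 3


@dataclass
class ComponentsConfig:
    connectivity: int = 8
    min_size: int = 20
    log_sigma: float = 3.0


@dataclass
class ContoursConfig:
    """mode "grow": each component is re-segmented from intensity-peak seeds
    (one outward-inflating contour per seed; splits merged nucleus clusters).
    mode "shrink": one contour per component, initialized just outside it and
    deflated onto the edges."""

    enabled: bool = True
    mode: str = "grow"
    v: float = -0.3            # balloon force in shrink mode (inward bias)
    grow_v: float = 0.7        # balloon force in grow mode (outward)
    dt: float = 0.25
    max_iters: int = 400
    grow_iters: int = 200
    reinit_every: int = 20
    smoothing_sigma: float = 2.0
    p: int = 2
    edge_gain: float = 30.0    # scales the H surface before the stopping map
    init_dilate_radius: int = 2
    seed_min_distance: int = 4
    seed_radius: int = 3
    margin: int = 10


@dataclass
class BlobsConfig:
    """``sigma`` is the Hessian blobness scale; the matched-filter choice is
    sigma = r/sqrt(2) for a target blob of effective radius r (lesions here
    have effective radius sqrt(a*b) ~ 8.5 px, hence the default 6.0)."""

    sigma: float = 6.0
    cutoff: float = 0.5


_SUB_CONFIGS = {
    "augment": AugmentConfig,
    "stain": StainConfig,
    "enhance": EnhanceConfig,
    "components": ComponentsConfig,
    "contours": ContoursConfig,
    "blobs": BlobsConfig,
    "detectnet": NetConfig,
}

# yaml serialization turns tuples into lists; these fields must come back
# as tuples for the round-trip to be value-identical
_TUPLE_FIELDS = {
    "morphology_sequence": lambda v: [(str(op), int(r)) for op, r in v],
    "shifts": lambda v: [tuple(s) for s in v],
    "widths": tuple,
}


@dataclass
class PipelineConfig:
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    stain: StainConfig = field(default_factory=StainConfig)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    components: ComponentsConfig = field(default_factory=ComponentsConfig)
    contours: ContoursConfig = field(default_factory=ContoursConfig)
    blobs: BlobsConfig = field(default_factory=BlobsConfig)
    detectnet: NetConfig = field(default_factory=NetConfig)
    match_dist: float = 5.0
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            sub = d[f.name]
            if f.name in _SUB_CONFIGS:
                sub = dict(sub)
                for key, conv in _TUPLE_FIELDS.items():
                    if key in sub:
                        sub[key] = conv(sub[key])
                sub = _SUB_CONFIGS[f.name](**sub)
            kwargs[f.name] = sub
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class PipelineResult:
    """Per-image record of every stage output that downstream steps need."""

    h_conc: np.ndarray
    stain_matrix: np.ndarray
    mask: np.ndarray
    partition: enh_mod.RegionPartition
    n_components: int
    candidates: list[blobs_mod.BlobCandidate]
    detections: list[blobs_mod.Detection]
    log_response: np.ndarray
    blobness: np.ndarray
    report: EvalReport | None = None


def _component_bbox(comp_mask: np.ndarray, margin: int):
    rows, cols = np.nonzero(comp_mask)
    H, W = comp_mask.shape
    r0, r1 = max(0, rows.min() - margin), min(H, rows.max() + 1 + margin)
    c0, c1 = max(0, cols.min() - margin), min(W, cols.max() + 1 + margin)
    return r0, r1, c0, c1


def _refine_shrink(comp_mask: np.ndarray, g_full: np.ndarray,
                   cfg: ContoursConfig) -> list[np.ndarray]:
    """One deflating contour per component, initialized slightly dilated."""
    r0, r1, c0, c1 = _component_bbox(comp_mask, cfg.margin)
    local = comp_mask[r0:r1, c0:c1]
    init = enh_mod.morphology(local, "dilate", cfg.init_dilate_radius)
    if init.all() or not init.any():
        return [comp_mask]
    u = cont_mod.init_levelset(init)
    params = cont_mod.EvolutionParams(
        v=cfg.v, dt=cfg.dt, max_iters=cfg.max_iters, reinit_every=cfg.reinit_every
    )
    u = cont_mod.evolve(u, g_full[r0:r1, c0:c1], params)
    if not (u < 0).any():
        return [comp_mask]
    refined = np.zeros_like(comp_mask)
    refined[r0:r1, c0:c1] = u < 0
    return [refined]


def _refine_grow(comp_mask: np.ndarray, g_full: np.ndarray,
                 cfg: ContoursConfig) -> list[np.ndarray]:
    """Seeded re-segmentation of one component.

    Seeds are the local maxima of the component's smoothed Euclidean
    distance transform (the hematoxylin surface is near-constant inside a
    nucleus, so its smoothed maxima cannot separate touching nuclei, while
    distance-transform maxima sit near individual nucleus centers); each
    seed inflates a contour (balloon ``grow_v``) that
    the stopping map locks onto nucleus edges, including the internal edges
    between overlapping nuclei.  Pixels claimed by several seeds go to the
    nearest seed; each claim clipped to the component becomes one mask, so a
    merged cluster of nuclei is split into per-nucleus candidates.
    """
    from skimage.feature import peak_local_max

    r0, r1, c0, c1 = _component_bbox(comp_mask, cfg.margin)
    local = comp_mask[r0:r1, c0:c1]
    seed_surface = ndi.gaussian_filter(ndi.distance_transform_edt(local), 1.0)
    seeds = peak_local_max(
        seed_surface, min_distance=cfg.seed_min_distance,
        labels=local, exclude_border=False,
    )
    if len(seeds) == 0:
        seeds = np.array([np.argwhere(local).mean(axis=0).round().astype(int)])
    rr, cc = np.mgrid[0 : r1 - r0, 0 : c1 - c0]
    params = cont_mod.EvolutionParams(
        v=cfg.grow_v, dt=cfg.dt, max_iters=cfg.grow_iters,
        reinit_every=cfg.reinit_every,
    )
    g_local = g_full[r0:r1, c0:c1]
    claims = []
    for sr, sc in seeds:
        init = (rr - sr) ** 2 + (cc - sc) ** 2 <= cfg.seed_radius**2
        if init.all() or not init.any():
            continue
        u = cont_mod.evolve(cont_mod.init_levelset(init), g_local, params)
        claims.append((u < 0) & local)
    if not claims:
        return [comp_mask]
    # contested pixels go to the nearest seed
    n_claimed = np.sum(claims, axis=0)
    contested = n_claimed > 1
    if contested.any():
        seed_d = [np.hypot(rr - sr, cc - sc) for sr, sc in seeds]
        nearest = np.argmin(seed_d, axis=0)
        for k in range(len(claims)):
            claims[k] = claims[k] & (~contested | (nearest == k))
    out = []
    for claim in claims:
        if not claim.any():
            continue
        full = np.zeros_like(comp_mask)
        full[r0:r1, c0:c1] = claim
        out.append(full)
    return out or [comp_mask]


def process_image(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    selection_model: blobs_mod.SelectionModel | None = None,
    stain_matrix: np.ndarray | None = None,
) -> PipelineResult:
    """Run every stage on one RGB image.

    Without a fitted ``selection_model`` all candidates are kept (the
    selection stage is a no-op); with one, only candidates whose selection
    score clears the cutoff become detections.
    """
    if config is None:
        config = PipelineConfig()
    od = stain_mod.rgb_to_od(img)
    if stain_matrix is None:
        params = stain_mod.MacenkoParams(alpha=config.stain.alpha, beta=config.stain.beta)
        stain_matrix = stain_mod.estimate_stain_matrix(od, params)
    conc = stain_mod.compute_concentrations(od, stain_matrix)
    h = conc[..., 0]
    logger.info("stain: matrix estimated, H conc range [%.3f, %.3f]", h.min(), h.max())

    mask = enh_mod.binary_threshold(
        h, config.enhance.threshold_method, config.enhance.threshold_level
    )
    for op, radius in config.enhance.morphology_sequence:
        mask = enh_mod.morphology(mask, op, radius)
    dist = enh_mod.distance_transform(mask)
    partition = enh_mod.partition_regions(
        mask, dist, config.enhance.fg_frac, config.enhance.bg_dilate_radius
    )
    logger.info("enhance: %d foreground px", int(mask.sum()))

    labels = comp_mod.label_components(mask, config.components.connectivity)
    masks = comp_mod.component_masks(labels, config.components.min_size)
    log_resp = comp_mod.log_response(h, config.components.log_sigma)
    logger.info("components: %d (of %d raw)", len(masks), int(labels.max()))

    n_components = len(masks)
    if config.contours.enabled and masks:
        g = cont_mod.stopping_map(
            h * config.contours.edge_gain,
            config.contours.smoothing_sigma,
            config.contours.p,
        ).g
        refined: list[np.ndarray] = []
        for mk in masks:
            if config.contours.mode == "grow":
                refined.extend(_refine_grow(mk, g, config.contours))
            else:
                refined.extend(_refine_shrink(mk, g, config.contours))
        masks = [mk for mk in refined
                 if mk.sum() >= config.components.min_size]

    blobness = blobs_mod.hessian_blobness(h, config.blobs.sigma)
    candidates = [blobs_mod.make_candidate(mk, blobness) for mk in masks]
    logger.info("candidates: %d", len(candidates))

    if selection_model is not None:
        detections = blobs_mod.score_and_select(
            candidates, selection_model, config.blobs.cutoff, frame_shape=h.shape
        )
    else:
        detections = []
        for cand in candidates:
            rows, cols = cand.pixels[:, 0], cand.pixels[:, 1]
            bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
            dm = np.zeros(h.shape, bool)
            dm[rows, cols] = True
            detections.append(blobs_mod.Detection(cand.centroid, bbox, dm, 1.0))
    logger.info("detections: %d", len(detections))

    return PipelineResult(
        h_conc=h, stain_matrix=stain_matrix, mask=mask, partition=partition,
        n_components=n_components, candidates=candidates, detections=detections,
        log_response=log_resp, blobness=blobness,
    )


def _candidate_labels(result: PipelineResult, scene) -> np.ndarray:
    """True iff a candidate's centroid falls in a lesion's ground-truth label."""
    labels, _ = ground_truth(scene)
    lesion_ids = {k for k, n in enumerate(scene.nuclei, start=1) if n.is_lesion}
    out = []
    for cand in result.candidates:
        r, c = (int(round(v)) for v in cand.centroid)
        r = np.clip(r, 0, labels.shape[0] - 1)
        c = np.clip(c, 0, labels.shape[1] - 1)
        out.append(labels[r, c] in lesion_ids)
    return np.asarray(out, bool)


def fit_pipeline_selection_model(scenes, config: PipelineConfig | None = None):
    """Fit the false-positive elimination model on synthetic training scenes.

    Candidates are labeled positive when their centroid lands inside a
    ground-truth lesion region.  Returns the fitted SelectionModel.
    """
    if config is None:
        config = PipelineConfig()
    all_cands: list[blobs_mod.BlobCandidate] = []
    all_labels: list[np.ndarray] = []
    for scene in scenes:
        img = render_rgb(scene)
        result = process_image(img, config, stain_matrix=scene.stain_matrix)
        all_cands.extend(result.candidates)
        all_labels.append(_candidate_labels(result, scene))
    labels = np.concatenate(all_labels) if all_labels else np.empty(0, bool)
    return blobs_mod.fit_selection_model(all_cands, labels)


def run_pipeline(
    images,
    config: PipelineConfig | None = None,
    selection_model: blobs_mod.SelectionModel | None = None,
    truth_centroids=None,
) -> list[PipelineResult]:
    """Process a list of images; attach an EvalReport per image when the
    matching list of ground-truth centroids is given."""
    if config is None:
        config = PipelineConfig()
    results = []
    for i, img in enumerate(images):
        result = process_image(img, config, selection_model)
        if truth_centroids is not None:
            result.report = evaluate_detections(
                [d.centroid for d in result.detections],
                truth_centroids[i],
                config.match_dist,
            )
        results.append(result)
    return results
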