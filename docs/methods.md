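# Methods

This note records the model underlying each stage, the parameter and
numerical choices, what the synthetic evaluation does and does not
demonstrate, and the known limitations. Coordinates everywhere are
0-based `(row, col)` with pixel centers at integer coordinates and
half-open bounding boxes.

## 1. Image model and synthetic scenes

**Beer–Lambert.** A pixel's optical density is
`OD = -log10(I / I0)` with `I0 = 1`; a stained pixel satisfies
`OD = M · c` with `M` the 3×2 matrix of unit stain absorbance vectors
(columns: hematoxylin, eosin) and `c ≥ 0` the concentrations. The
generator renders exactly this model: `I = 10^(−M·c)`, with optional
i.i.d. Gaussian noise of standard deviation `noise_sd` added in OD space
(clipped at 0).

**Scene content.** Nuclei are ellipses with semi-axes `a ≥ b`; normal
nuclei use `a ∈ [5, 8]` px and hematoxylin concentration
`h ∈ [0.45, 0.75]`, lesions `a ∈ [8, 12]` and `h ∈ [1.0, 1.4]` — larger
and denser, which is the only property separating the two classes.
Within a nucleus, eosin is displaced to zero (nuclei are near-pure
hematoxylin); the background carries small hematoxylin (0.05) and
moderate eosin (0.25) baselines. Two kinds of distractors can be added:

- *clutter*: elongated, fiber-like ellipses with moderate hematoxylin —
  they threshold into foreground but are not blob-shaped, exercising the
  false-positive elimination stage; they carry no ground-truth label;
- *eosin patches*: densely eosinophilic ellipses (`e ≈ 2.2`,
  erythrocyte-cluster-like). These matter for estimability: Macenko's
  filter keeps only pixels with OD above β in **all** channels, and with
  a pale pink background no near-pure-eosin pixel would survive it; the
  patches guarantee both stain directions are represented in the kept
  OD cloud.

**Placement.** A configurable fraction of nuclei is placed so the
ellipse genuinely intersects an earlier "anchor" nucleus (verified on a
dense grid), center within one anchor semi-major axis; the rest are
pairwise disjoint. No center (including its rounded pixel) may fall
inside another nucleus's ellipse, so in the ground-truth label image —
where overlapping pixels go to the higher-concentration nucleus — every
nucleus retains at least its own center pixel. If placement fails after
`max_tries` attempts a `PlacementError` is raised rather than returning
a degenerate scene.

**What the synthetic data shows / does not show.** Because ground truth
(stain matrix, concentration fields, per-nucleus labels, lesion
centroids) is exact, the scenes give sharp quantitative checks of each
stage: stain-vector recovery to fractions of a degree, exact
concentration round-trips, contour locking to sub-pixel radial error,
and end-to-end precision/recall. They do **not** demonstrate performance
on real tissue: real nuclei have textured chromatin, irregular borders,
out-of-focus blur and staining gradients; real stain vectors vary across
labs; and real lesion/normal separation is not a clean size+density
offset. All end-to-end numbers here are upper bounds specific to this
generative model.

## 2. Stain normalization (Macenko)

- OD conversion floors intensities at `1/255` so 8-bit black maps to a
  finite OD (~2.41).
- β-filter: keep pixels with OD > β (default 0.15) in *all three*
  channels; fail with `StainEstimationError` when nothing survives
  (blank or overexposed input).
- The two leading right-singular vectors of the kept OD rows span the
  stain plane; the extreme directions at the α and 100−α angle
  percentiles (α = 1) become the stain vectors, sign-fixed to be
  non-negative and normalized to unit length.
- **Column identity:** hematoxylin is the column with the larger
  red-to-blue OD ratio. Blue-appearing hematoxylin absorbs red light,
  so its absorbance vector (≈ (0.65, 0.70, 0.29) after normalization)
  is red-heavy; eosin (≈ (0.07, 0.99, 0.11)) is green-heavy.
- Concentrations come from least squares with a per-pixel NNLS fallback
  wherever the unconstrained solution goes negative; normalization to a
  reference rescales each concentration channel so its 99th percentile
  matches the reference before re-rendering under the reference matrix.

**Known bias.** With OD noise 0.02, the eosin vector is recovered to a
median ~0.2°, but the hematoxylin vector carries a systematic ~3.5°
error. This is an inherent property of the percentile rule on this
geometry: on a two-ray OD cloud, the 1st-percentile angle sits ~2.3
standard deviations into the noise tail of the faintest pure-H pixels,
and the β threshold additionally clips the H ray asymmetrically at the
blue-channel boundary. The pooled median over both vectors (~1.7°) is
the headline number; the per-column asymmetry is reported here rather
than hidden by retuning the generator.

## 3. Enhancement

Otsu's threshold on the hematoxylin surface (error on degenerate
single-value histograms), then a configurable sequence of disk-element
morphology (default: one opening of radius 1). Morphology uses the
border convention "out-of-frame pixels are ignored" (erosion pads with
foreground, dilation with background), which preserves the duality
`dilate(m) = ~erode(~m)` exactly — property-tested. The distance
transform partitions the frame into sure foreground (distance >
`fg_frac`·max), sure background (outside the mask dilated by 3 px), and
an unknown rim; the three masks are disjoint and exhaustive by
construction.

## 4. Segmentation: components + geodesic active contours

Connected components (8-adjacency, minimum size 20 px) give coarse
masks. The level-set refinement solves

```
du/dt = g(I)·(κ − v)·|∇u| + ∇g · ∇u ,   u < 0 inside
```

with `g = 1/(1 + |∇(G_σ∗I)|^p)` built from the hematoxylin surface
scaled by `edge_gain`.

Numerical choices, each validated by a closed form:

- **Explicit scheme, dt = 0.25** (2D stability bound): central
  differences for the curvature term, Godunov upwinding for the balloon
  term, one-sided upwinding for the advection term.
- **Sub-pixel reinitialization every 20 iterations:** pixels adjacent to
  a sign change keep the first-order estimate `u/|∇u|`; the rest get
  that estimate propagated by an EDT. A plain pixel-grid EDT
  reinitialization re-snaps the front to the grid and biases the motion
  by 5–20% on the circle-shrinkage law `r(t)² = r0² − 2t`; the sub-pixel
  variant holds the law within 5% down to r ≈ 5 px.
- **edge_gain = 30:** chosen by a convergence study on noiseless disks.
  A very deep g-pit (gain 100) freezes the front ~2 px short of the
  edge for thousands of iterations; gain 30 leaves enough advection to
  lock the front to ~0.1 px mean radial error in 400 iterations. The
  calibration used disk phantoms only, not the end-to-end fixture.
- **Seeded "grow" mode (default):** within each component, seeds are
  local maxima of the smoothed distance transform (minimum separation
  4 px); each seed inflates a small disk (balloon v = +0.7) until the
  stopping map halts it, contested pixels go to the nearest seed, and
  claims are clipped to the component. This splits merged nucleus
  chains. The hematoxylin surface itself cannot provide the seeds: it is
  near-constant inside nuclei, so a merged chain of equal-concentration
  nuclei smooths into a single plateau peak. A consequence is that the
  number of candidates can exceed the raw component count; the pipeline
  funnel invariant is "detections ⊆ candidates". A one-contour-per-
  component "shrink" mode is also available.

## 5. Blob scoring and selection

The Laplacian-of-Gaussian kernel is evaluated symbolically on the
integer grid (center weight exactly `−2/σ²`). Blobness uses the
Gaussian-derivative Hessian at scale σ with reflect boundary handling
(constant-padding would fabricate blobs along the frame edge); with
eigenvalues λ1 ≤ λ2 scale-normalized by σ², the score is
`sqrt(λ1·λ2)` where λ2 < 0 and zero elsewhere — bright elliptical blobs
score high, ridges and dark blobs score zero or near zero.

**Scale choice σ = 6.0:** the matched-filter rule σ = r/√2 for a target
of effective radius `r = sqrt(a·b) ≈ 8.5` px (the generator's lesions).
A mismatched σ = 3 (tuned to normal-nucleus size) degrades
lesion-vs-rest separability of the blobness features (per-feature AUC
0.96 vs ~1.00 at σ = 6, measured on training scenes disjoint from the
evaluation fixture).

The selection function `Ls(T) = sigmoid(β0 + Σ βi·xi)` uses exactly
three features (blobness mean, blobness max, size), standardized
internally, fitted by Newton/IRLS to convergence `max|Δβ| < 1e-8`.
Perfect separation (unbounded likelihood) is detected via
non-convergence or exploding coefficients and answered with a warning
and a ridge-penalized refit. Candidates with `Ls ≥ 0.5` become
detections. The fit is verified against a coarse-to-fine grid-search
oracle (agreement ~1e-8) and recovers generating coefficients within
fractions of a standard error at n = 2000.

## 6. Dense detection network

A numpy feed-forward network — dense widths (64, 64, 32, 16) with a
dropout layer (rate 0.2) after each hidden dense layer and a softmax
output, trained with Adam (lr 1e-4, batch 32, 30 epochs), categorical
cross-entropy, 20% validation split, and early stopping (patience 5)
that restores the best-validation weights. Inputs are per-candidate
feature vectors (size, blobness stats, eccentricity, solidity,
hematoxylin stats), not raw pixels. Training is fully deterministic
given the seed.

**Regularization contrast (honest reading).** At these problem sizes
(~100 candidates, 30 epochs, lr 1e-4) the network barely overfits, so
the dropout+early-stopping vs no-regularization gap contrast is real
but small: median final-model validation-minus-train loss gap over 10
seeds is lower with regularization (e.g. 0.031 vs 0.043 on the fixture
split), with individual seeds occasionally flipping. The acceptance test
asserts only the median ordering.

## 7. Evaluation

Greedy one-to-one matching of detection centroids to ground-truth
lesion centroids by ascending distance, valid within 5 px. Greedy
matching is not optimal assignment; a test asserts its match count
never exceeds the Hungarian optimum. Undefined precision/recall (empty
prediction or truth sets) is reported as 0 with an explicit
`*_defined = False` flag.

**End-to-end result.** On the standard fixture (20 scenes, seeds 0–19,
20 nuclei, 30% overlap, lesion fraction 0.3, 4 clutter fibers, OD noise
0.02; selection model trained on scenes with seeds 100–107):
precision 1.000, recall 0.917. On disjoint seed ranges (200–219,
500–519) recall is 0.900 and 0.892 with precision ≥ 0.98 — the
criterion margin is thin. The residual misses are deeply overlapped
lesion pairs whose merged mask has a single distance-transform peak, so
no second seed exists to split them; fixing this would need joint model
fitting (e.g. mixture-of-ellipses) rather than parameter adjustment,
and is out of scope.

## 8. Limitations

- All quantitative claims are on synthetic scenes drawn from the
  package's own generative model (§1); nothing here certifies clinical
  performance.
- The Macenko H-vector percentile bias (§2) caps stain-recovery
  accuracy at ~3–4° for the faint-tail stain under noise; α could be
  tuned per-noise-level, but is deliberately kept at the standard value.
- Deeply overlapped same-class nuclei (center separation below the seed
  resolution) are detected as one object (§7).
- The explicit level-set scheme needs hundreds of iterations per
  component; it is fast at these image sizes but would need a
  narrow-band or sparse-field implementation for whole-slide use.
- The detection network adds little over the 3-feature logistic model
  on this data — the synthetic classes are nearly separable in the
  logistic features already; it is exercised and tested, but the
  pipeline's default detections come from the logistic stage.
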