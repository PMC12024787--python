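# histoblob

Automatic blob detection of cancerous lesions in H&E-stained breast
histology images: Macenko stain normalization, morphological enhancement,
connected-components segmentation refined by geodesic active contours,
Hessian-blobness candidate scoring with logistic false-positive
elimination, and a small dense detection network — packaged as a library
and a `histoblob` command-line tool, with a fully synthetic H&E scene
generator for development and evaluation.

## The science in brief

Hematoxylin stains nuclei blue-purple; eosin stains stroma and cytoplasm
pink. In optical density (OD) space, `OD = -log10(I)`, a stained pixel is
(by Beer–Lambert) a *non-negative linear combination* of the two stain
absorbance vectors. The pipeline exploits this linearity end to end:

1. **Stain estimation (Macenko).** Pixels with OD above a threshold β in
   all channels are projected onto the plane of the two leading singular
   vectors of the OD cloud; the extreme directions at the α / (100−α)
   angle percentiles are the stain vectors. The column whose red-to-blue
   OD ratio is larger is hematoxylin. Non-negative least squares then
   unmixes every pixel into (H, E) concentrations.
2. **Enhancement.** The hematoxylin concentration surface is Otsu
   thresholded and cleaned with disk-structuring-element morphology; the
   Euclidean distance transform splits the frame into sure
   foreground / sure background / unknown.
3. **Segmentation.** Connected components give coarse nucleus masks. Each
   component is re-segmented by geodesic active contours: seeds at the
   maxima of the component's distance transform each inflate a front that
   an edge-stopping map `g = 1/(1 + |∇(G_σ * I)|^p)` locks onto nucleus
   boundaries — splitting merged nucleus clusters into per-nucleus
   candidates.
4. **Blob scoring and selection.** A scale-normalized Hessian blobness
   score (geometric mean of the eigenvalues where both are negative, i.e.
   bright-blob-like) is summarized per candidate as (mean, max, size); a
   logistic selection function `Ls(T) = sigmoid(β₀ + Σ βᵢ xᵢ)` fitted by
   IRLS eliminates false positives (stromal fibers, clutter, normal
   nuclei). A small dense network (5 dense + 3 dropout layers, Adam,
   early stopping) is available as a second-stage classifier over richer
   per-candidate features.

There is no public dataset attached to this implementation, so a
**synthetic scene generator** is a first-class component: it places
elliptical nuclei (lesions are larger and more hematoxylin-dense),
elongated clutter fibers and eosinophilic patches, and renders the scene
through the exact Beer–Lambert model with OD-space noise. Because the
generator's ground truth (per-nucleus labels, lesion centroids, true
stain matrix) is exact, every stage can be evaluated quantitatively.

## Worked example

```python
from histoblob import (PipelineConfig, make_scene, render_rgb, ground_truth,
                       fit_pipeline_selection_model, process_image,
                       evaluate_detections)

config = PipelineConfig()

# fit the false-positive elimination model on training scenes
train = [make_scene(20, (128, 128), 0.3, 0.3, seed=100 + i, n_clutter=4,
                    noise_sd=0.02) for i in range(8)]
model = fit_pipeline_selection_model(train, config)

# detect lesions in a held-out scene
scene = make_scene(20, (128, 128), 0.3, 0.3, seed=3, n_clutter=4, noise_sd=0.02)
result = process_image(render_rgb(scene), config, selection_model=model)

_, lesion_centroids = ground_truth(scene)
report = evaluate_detections([d.centroid for d in result.detections],
                             lesion_centroids, match_dist=5.0)
print(f"components={result.n_components} candidates={len(result.candidates)} "
      f"detections={len(result.detections)}")
print(f"precision={report.precision:.3f} recall={report.recall:.3f} f1={report.f1:.3f}")
for d in result.detections[:3]:
    print(f"  lesion at ({d.centroid[0]:.1f}, {d.centroid[1]:.1f})  score={d.score:.3f}")
```

Output:

```
components=13 candidates=16 detections=6
precision=1.000 recall=1.000 f1=1.000
  lesion at (13.1, 67.0)  score=0.992
  lesion at (46.5, 33.4)  score=0.986
  lesion at (97.7, 26.0)  score=0.983
```

The same pipeline is available from the shell:

```
$ histoblob synth --n-nuclei 20 --overlap 0.3 --lesion-fraction 0.3 \
      --n-clutter 4 --noise-sd 0.02 --seed 3 --out s3.png --truth s3.json
wrote s3.png (20 nuclei, 6 lesions)
$ histoblob detect s3.png --model sel.json --out det3.json
s3.png: 6 detections (16 candidates)
$ histoblob eval --pred det3.json --truth s3.json
{"tp": 6, "fp": 0, "fn": 0, "precision": 1.0, "recall": 1.0, "f1": 1.0}
```

Subcommands: `synth`, `augment`, `normalize`, `enhance`, `components`,
`contours`, `blobs`, `train`, `detect`, `eval` (`histoblob --help` for
all options). Configuration is one YAML file mirroring
`PipelineConfig`; every stage also works on ordinary PNG/TIFF/JPEG
images, not only synthetic ones.

## Documentation

`docs/methods.md` describes the model and its assumptions, all numerical
choices (discretization, reinitialization, scale selection), what the
synthetic data does and does not demonstrate, and known limitations.
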