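# pollenmorph

Interpretable machine-learning classification of pollen particles on stained
brightfield slide images.

Routine aerobiological monitoring with gravimetric (Durham-type) slides
requires distinguishing cedar (*Cryptomeria japonica*) pollen, cypress
(*Chamaecyparis obtusa*) pollen, their burst/ruptured forms, and dust or
other artifacts under a light microscope. Manual counting is slow and
observer-dependent; black-box classifiers are hard to audit. `pollenmorph`
implements a fully transparent alternative: circle-based particle detection,
a small set of handcrafted morphological and textural descriptors, a
multicollinearity-aware feature-selection protocol, and a nested
cross-validated support-vector classifier whose every reported number is
reproducible from seeds.

The package is aimed at aerobiology and environmental-health groups who want
an auditable pipeline for slide-based particle classification, and ships a
ground-truthed synthetic slide generator so the entire pipeline is testable
without any microscopy data.

## What it computes

**Detection.** Circular candidates come from the circle Hough transform on a
Canny edge map; duplicate detections of the same grain are collapsed by
DBSCAN on the center coordinates, and a 512 × 512 px region is cropped
around each surviving center.

**Descriptors.** Eleven interpretable quantities per particle: the detected
radius *r*; circularity 4π·A/P²; the largest-inscribed-circle to detected
radius ratio; segmented area A (px); the shift ‖c_Hough − c_mask‖ between
detected center and mask centroid; box-counting fractal dimension of the
contour; the number of radial line segments (germinal-furrow analogue);
the center-minus-periphery intensity difference; Canny edge density; Shannon
entropy of the uniform LBP histogram; and the convex-hull defect ratio
1 − A_obj/A_hull. A refined **core-9** subset drops `fractal_dim` and
`edge_density`, which are redundant (high VIF) and less interpretable for
pollen walls.

**Selection.** Four criteria: Pearson correlation screening (|r| > 0.85),
variance inflation factors VIF_j = 1/(1 − R²_j) with flags at 5 and 10,
drop-column ablation under frozen cross-validation splits, and permutation
importance on out-of-fold data with cross-fold rank-stability summaries.
Exclusions are explicit, logged decisions — never automatic.

**Evaluation.** Nested stratified 5-fold cross-validation (outer seed 42,
inner seed 1) of the pipeline *z-score → RBF-SVM* over the grid
C ∈ {0.3, 1, 3, 10, 30}, γ ∈ {0.003, 0.01, 0.03, "scale"},
class_weight ∈ {none, balanced}, selected by inner macro-F1. Out-of-fold
predictions are aggregated into a row-normalized confusion matrix,
one-vs-rest ROC/PR curves with bootstrap confidence intervals,
class-prevalence baselines, and macro-F1 mean ± SD with its
Student-t 95% interval.

## Worked example

```python
from pollenmorph import synthscene as ss, detect as dt, features as ft

# render a small ground-truthed slide and detect the particles
spec = ss.sample_scene({"cedar": 2, "cypre": 2, "dust": 2}, seed=4,
                       width=1024, height=1024, noise_sd=3.0)
image, truth = ss.render_scene(spec)
dets = dt.dedup_detections(
    dt.detect_circles(image, dt.HoughParams(min_radius=8)), eps=25.0)
print(f"{len(truth)} particles rendered, {len(dets)} candidates detected")

best = max(dets, key=lambda d: d.score)   # strongest circle
vec = ft.extract_all(dt.crop_particle(image, best))
for name, value in ft.to_core9(vec).items():
    print(f"{name:>16s}  {value:8.3f}")
```

prints

```
6 particles rendered, 7 candidates detected
          radius    96.000
  centroid_shift     0.473
     circularity     0.992
       spike_cnt     3.000
 texture_entropy     2.964
         area_px  28698.000
     radial_grad    -4.159
 inscribed_ratio     0.989
convex_def_ratio     0.007
```

The strongest detection is a large cedar-like grain: nearly perfectly
circular (circularity 0.992, hull defect 0.007), almost exactly filling its
detected circle (inscribed ratio 0.989), with the three rendered radial
furrows recovered by `spike_cnt`. One of the seven candidates is a spurious
circle that truth-matching would discard.

The same flow runs from the shell:

```sh
pollenmorph simulate --out scenes/ --seed 0 --n-scenes 2
pollenmorph run --out results/ --seed 1
```

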