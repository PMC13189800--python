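# Methods

## Problem setting and model

The pipeline classifies individual particles cropped from stained
brightfield slide images into five classes — intact cedar pollen (`cedar`),
intact cypress pollen (`cypre`), their burst forms (`cedar_brst`,
`cypre_brst`), and dust/miscellaneous artifacts (`dust`). The classifier is
deliberately shallow and auditable: a radial-basis-function support-vector
machine over a handful of handcrafted descriptors, so that every decision
can be traced to interpretable morphology (size, shape regularity, boundary
concavity, radial furrow structure, internal texture).

Core assumptions:

* particles are stained and therefore **darker than the background**; all
  foreground logic keys off this (with polarity auto-detection as a guard);
* intact grains are approximately circular, so a circle detector is an
  adequate candidate generator and the detected radius is a meaningful size
  descriptor;
* burst grains deviate from the disk by ruptured, concave outlines and
  extruded material — captured by the hull-defect ratio, circularity,
  centroid shift and inscribed ratio;
* cedar-like grains are systematically larger than cypress-like grains with
  overlapping ranges, so size descriptors carry most of the signal and
  shape/texture descriptors refine it.

## Pipeline stages and tunable parameters

### Detection (`detect`)

Canny edges (σ = 2 px; thresholds at quantiles 0.90/0.98 of the gradient
magnitude so only the strongest ~10 % of gradients seed edges) feed a circle
Hough transform over radii 20–110 px in 2-px steps (8–110 px when dust must
be found). Peaks need accumulator support ≥ 0.35 of the circle perimeter and
at least 50 px separation — about the smallest intact radius, so distinct
grains are never merged while duplicate peaks of one grain survive to the
dedup stage. An optional integer `downscale` runs the transform at reduced
resolution (default 2 in the end-to-end pipeline; ~8× faster at ~2 px
center/radius quantization, which is far below the 20-px truth-matching
tolerance).

Duplicates are collapsed by DBSCAN over center coordinates with
eps = 25 px (~0.5 × the smallest intact radius) and min_samples = 1; each
cluster is represented by its largest-radius member, ties broken toward the
smallest (y, x). Crops are 512 × 512 with half-open pixel ranges, 0-based
(x = column, y = row) coordinates; out-of-image regions are filled with the
median of the image's 1-px border frame rather than zeros, so the padding
introduces no artificial step edges into the Canny-based descriptors. The
fill value is recorded on the crop.

### Descriptors (`features`)

Numerical conventions that the descriptor values depend on:

* **Binarization** — Otsu threshold on the grayscale crop; the foreground is
  the side of the threshold containing the crop-center 11 × 11 neighborhood
  mean (making the mask invariant to intensity inversion); largest connected
  component kept, holes filled. A constant crop yields an empty, flagged
  mask.
* **Perimeter** — arc length of the marching-squares 0.5-level contour after
  Douglas-Peucker simplification at 1-px tolerance. The simplification
  removes the pixel-staircase bias (~5–6 % overestimation on smooth curves):
  a digitized r = 100 disk measures circularity 0.996, a side-100 square
  0.793 (analytic π/4 = 0.785), a 1 × 100 bar 0.031.
* **Canny thresholds** — quantiles 0.90/0.97 of the σ = 2 smoothed gradient
  magnitude. Quantile thresholds adapt to each crop's contrast; a
  median-multiple rule was rejected because it degenerates when most of the
  crop is flat.
* **Spike count** — probabilistic Hough segments (threshold 30, minimum
  length max(20, 0.6 r), gap 2, fixed sampling seed) filtered to midpoints
  within 1.5 r of the center and directions within 20° of radial. Segments
  whose midpoint polar angles agree within 15° are merged: the two Canny
  side-edges and any fragments of one furrow share the furrow's polar angle,
  so this single rule deduplicates both.
* **LBP texture entropy** — 8 neighbors, radius 1, rotation-invariant
  uniform binning (10 bins), Shannon entropy in bits over mask-interior
  pixels (mask eroded by 2; fewer than 16 interior px → NaN, flagged).
* **Box counting** — grid sizes 2–64 px (powers of two) anchored at the crop
  origin, least-squares slope of log N vs log(1/s); contours under 8 px or
  fewer than 4 usable scales → NaN, flagged.
* **Radial gradient** — mean intensity inside the disk of radius r/3 minus
  the annulus (2r/3, r], both about the detected center; NaN when the
  annulus misses the image entirely.
* **Edge density** — Canny edge pixels inside the mask bounding box divided
  by the box area. The bounding box (not the mask area) is the denominator;
  recorded here because "region size" admits both readings and the choice
  shifts absolute values.

Degenerate inputs produce NaN plus a named flag on the feature vector, and
flagged records are excluded downstream with a logged count — they are never
silently imputed.

### Selection (`select`)

VIF is computed on the full, unsplit z-scored matrix — it diagnoses the
design, not the model, so fold-wise computation would only add noise.
Drop-column ablation re-runs the complete nested CV per candidate feature
set with bit-identical fold assignments (asserted via fold hashes).
Permutation importance permutes columns within the held-out fold of each
fitted outer-fold model (10 repeats by default, seeded); restricting the
shuffle to evaluation data keeps the fitted models fixed across features.
The "biological validity" criterion is an expert judgment: it enters the
decision log as free text, never as a computation. Ties in ablation are
reported, not auto-resolved — exclusions are explicit config inputs.

### Evaluation (`evaluate`)

Nested stratified 5-fold CV: outer StratifiedKFold(shuffle, seed 42), inner
StratifiedKFold(shuffle, seed 1), grid C ∈ {0.3, 1, 3, 10, 30},
γ ∈ {0.003, 0.01, 0.03, "scale"}, class_weight ∈ {none, balanced}.
Standardization is fit on outer-training data only. Design choices where the
protocol was genuinely open:

* **Inner scoring** is macro-F1 (the primary end metric); balanced accuracy
  is available as a config alternative.
* **Tie-breaking** over the grid is fixed: smaller C first, then smaller γ
  with "scale" last, then class_weight none first. The inner search iterates
  in exactly this order and keeps the first strict maximum.
* γ = "scale" means 1/(n_features × Var(X)) evaluated on the standardized
  training matrix (i.e. ≈ 1/n_features).
* The discrete out-of-fold prediction is the SVM's **direct decision**; the
  per-class probabilities come from the classifier's internal Platt-style
  calibration fit on training data. Both are stored because they can
  disagree. The inner search skips probability calibration entirely — it
  only needs discrete predictions, which calibration does not change, and
  this makes the search ~5× cheaper.
* Fold scores are summarized as mean ± sample SD with the Student-t 95 %
  interval mean ± t(0.975, n−1)·SD/√n, reported unclipped even when it
  leaves [0, 1].
* ROC AUC is trapezoidal; AUPRC is the step-integrated average precision;
  CIs are percentile intervals from a stratified bootstrap over out-of-fold
  samples (2,000 resamples by default, seeded). Each PR curve carries its
  class-prevalence no-skill baseline.
* Group-aware (slide-level) fold assignment is intentionally not the
  default: samples are stratified at the particle level, and the resulting
  non-independence of crops from one slide is a documented limitation, not
  something the desk-scale protocol can fix.

## Synthetic scene generator (`synthscene`)

The generator emulates what makes routine slides hard: two overlapping size
classes of dark, near-circular grains (cedar-like radius 72–96 px with 1–3
radial furrow lines; cypress-like 52–76 px, smooth), burst variants (swollen
radius, an angular sector of 18–42 % of the disk removed, 1–3 extruded
blobs at the rupture), small irregular dust polygons (radius 8–22 px, below
half the smallest intact radius so size alone separates them), background
intensity gradients, bubble-like rings, and additive Gaussian sensor noise.
Furrow lines keep ≥ 50° angular separation so the rendered truth for
`spike_cnt` is unambiguous. All rendering is driven by one integer seed and
is bit-reproducible.

What it does **not** emulate — and hence what passing tests do not show
about real slides: staining chemistry and its intensity variability, optical
blur and depth-of-field effects, overlapping/touching grains, non-target
pollen taxa, and the full morphological heterogeneity of real burst grains.
Synthetic performance numbers characterize the pipeline's mechanics
(detection geometry, descriptor correctness, protocol integrity), not
field accuracy.

Default problem sizes: unit tests render single 512² crops; end-to-end runs
use 8–10 scenes of 1024² with ~15 particles each (~100 crops), which keeps
a full run with the complete hyperparameter grid under a couple of minutes
on one CPU while every class still clears the ≥ 2-samples-per-fold
stratification floor.

## Known limitations

* The Hough stage assumes one dominant circle per neighborhood; heavily
  overlapping grains produce merged or spurious candidates that only the
  truth-matching (synthetic) or expert labeling (real data) step removes.
* `spike_cnt` counts line-like furrows; curved or foreshortened apertures
  are undercounted by design.
* The descriptor set is resolution-bound: thresholds (minimum line lengths,
  box-count scales, LBP radius) are in pixels and assume crops near the
  512-px scale at ~400× magnification; images at other scales need rescaled
  parameters, not silent reuse.
* Reported CIs treat particles as independent; when many crops come from one
  slide, the bootstrap and t-intervals are optimistic.
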