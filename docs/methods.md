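# Methods

`planeye` quantifies two things about planarian eyes from standard inputs:
(1) the number of marker-positive (e.g. *opsin*⁺) photoreceptor neurons in
two-channel confocal z-stacks, and (2) the positions of ectopic eyes and
migratory eye progenitors across animals of different sizes, expressed in a
common coordinate frame anchored to the two original eyes. This note
documents the models, the defaults, the synthetic-data generators used for
validation, and the numerical conventions.

## 1. Counting estimator

### Model

For each sample, 2D slices are taken from the z-stack at a fixed physical
interval (default 5 µm). On each sampled slice, nuclei are segmented in the
nuclear-stain channel; each nucleus ROI is called marker-positive when the
**median** marker-channel intensity over its pixels **strictly exceeds** a
global threshold; per-slice positive counts are summed over the stack.

The sum is an **abundance index**, not a deduplicated 3D cell count: a
nucleus of radius r intersects 0, 1 or 2 sampled planes depending on r
versus the sampling interval, so the index scales with — but does not equal
— the true cell number. All downstream inference therefore uses
*between-group differences* of the index under identical parameters, and a
robustness sweep verifies that the direction of the difference is unchanged
across threshold multipliers {0.9, 1.0, 1.1} and sampling intervals
{2.5, 5, 7.5, 10} µm.

### Threshold

The positivity threshold comes from Otsu's criterion applied to the pooled
marker-channel pixels of the slices that contain target-cell signal. The
implementation is an exact-value Otsu: candidate thresholds are midpoints
between consecutive distinct intensity values, and the returned threshold
maximizes the between-class variance w₀w₁(µ₀−µ₁)², with ties broken toward
the lowest qualifying threshold. This avoids a histogram-binning choice for
float data and keeps the strict "median > threshold" call unambiguous. A
constant sample has no threshold and is an error.

"Slices that contain target cells" is operationalized as: slices whose
smoothed (σ = 1 px) marker-channel maximum exceeds the stack-wide
`background_quantile` (default 0.95) of smoothed intensities. This rule is
a documented choice — any rule that excludes empty slices works — and is
configurable (`slice_rule: all` pools every slice). The threshold scope
defaults to per-animal (both head sides pooled, since the two sides of one
animal are imaged under equivalent settings); per-stack scope is available.

### Segmentation

The default backend is a classical watershed pipeline: Gaussian smoothing
(σ = 1 px) → optional rolling-ball background subtraction (off by default;
synthetic backgrounds are flat) → global Otsu foreground threshold →
Euclidean distance transform → peak seeds with a minimum separation
(5 px) → watershed → area filter (inclusive bounds, default 20–2500 px²)
and border filter (ROIs touching the slice border are dropped by default,
because partial nuclei bias the median intensity). Seeds are labelled in
(row, column) order, which makes the output deterministic.

The backend is pluggable behind a registry keyed by name. Any backend must
emit ROIs with unique labels and disjoint pixel sets per slice (audited at
run time). An adapter for the StarDist 2D deep-learning segmenter registers
itself when that package is installed; the published operating point
(probability threshold 0.60, NMS threshold 0.5) is recorded in the
configuration defaults for that backend. The classical backend is the
reference for all tests: the estimator only requires nucleus *detection*
plus pixel support for the median, not the specific segmenter.

### Slice sampling

Indices are `round(k · interval / z_spacing)` for k = 0, 1, … while the
index is below the stack size, with round-half-to-even and duplicate
collapse. Any deterministic rounding rule would do; half-to-even is
unbiased. The interval must be ≥ the z spacing.

### Group comparison

Totals are compared with an unpaired two-tailed Student t-test (pooled
variance), implemented in closed form with the t-distribution CDF. Zero
pooled variance with equal means returns t = 0, p = 1; with unequal means
the statistic is undefined and raises.

## 2. Segmentation QC (Jaccard index)

Predicted detections are matched to annotated cells greedily by ascending
centroid distance within a match radius (default 2.5 µm, the mean nucleus
radius; always declared in the report). Remaining predictions are FP,
remaining annotations FN, and JSI = TP/(TP+FN+FP). Per-sample JSIs are
compared between treatment groups with the same pooled t-test, answering
whether segmentation/counting efficiency differs between treatments.

Greedy matching was chosen over optimal assignment for transparency. On
detection-like geometry — cells separated by more than twice the match
radius, as enforced by the synthetic generator (5.5 µm minimum center
distance vs 2.5 µm radius) — greedy attains the maximum-cardinality
matching; the test suite verifies this against a brute-force enumeration
oracle on all instances of ≤ 8 points and additionally checks that greedy
never exceeds the optimum on adversarially crowded instances (where it can
fall short; such geometry does not arise for well-separated nuclei). Ties
in distance are broken by (predicted id, truth id) order.

## 3. Spatial normalization

Each animal's left/right original-eye landmarks define a similarity
transform: translate the eye midpoint to the origin, rotate the inter-eye
axis onto x with the left eye at negative x, scale by 2/(inter-eye
distance), and compose a y-flip if the declared anterior indicator would
land in the y ≤ 0 half-plane. The eyes map exactly to (−1, 0) and (1, 0);
one unit is half the inter-eye distance; y > 0 is anterior.

Conventions and edge rules:

* Pixel coordinates are 0-based, x = column, y = row, **y increasing
  downward**; the anterior direction is supplied per animal and never
  inferred from image content.
* The anterior vector must be ≥ 5° off the inter-eye axis (configurable);
  closer is ambiguous and raises.
* The posterior-most ectopic eye is the minimum-y ectopic point; ties are
  broken by larger |x|, then input order (a convention of this package —
  real data never needed one).
* "Anterior" counts use strict y > 0; points on the axis do not count.
* Original-eye points of reference animals are mapped like any other point,
  enabling control-eyes-vs-ectopic-eyes overlays.

Normalized coordinates are invariant (to 1e-9) under any similarity
transform of the pixel data, and a left-right mirror of the pixel data
negates x and fixes y; both are property-tested.

## 4. Synthetic-data generators

Because no raw imaging data accompany the workflow, validation uses two
ground-truthed generators.

**Stacks.** Nuclei are hard spheres on a calibrated voxel grid (pixel
centers at (i+0.5)·pixel_size in x/y; plane k at k·z_spacing in z), with
optional isotropic-in-plane Gaussian blur (`blur_sigma_px`, default 0 so
that, without noise, voxels outside every sphere are exactly zero — a
property the tests exploit with an exhaustive voxel scan). Default geometry
emulates the imaging the estimator targets: 0.3 µm slices, 0.5 µm pixels,
~2.5 µm nucleus radii, minimum center distance 5.5 µm. Marker intensity is
a per-cell constant (180 a.u. positive vs 20 a.u. negative over a 5 a.u.
background) so the per-ROI median is a clean statistic; Gaussian read noise
(default σ = 4 a.u.) and optional Poisson shot noise are applied last, then
clipped at zero. The marker-positive subset has exactly
round(fraction·n_cells) members, drawn with the stack's seed, so a sample's
true count is controlled. Placement is rejection sampling with a cap of
10 000 attempts per cell; exceeding the cap raises an error naming the
distance constraint. Not emulated: PSF anisotropy, channel bleed-through,
depth attenuation, pigment cups — so passing tests demonstrate correctness
of the *computation*, not robustness to every optical artifact of real
confocal data.

**Animal populations.** True ectopic-eye and progenitor positions are drawn
in normalized coordinates from per-type 2D Gaussian mixtures (weights sum
to 1). Preset mixtures encode the phenotype classes the mapping is used to
distinguish: a broad bilateral posterolateral cloud (components at
(±1.5, −1.5)), a tight directly-posterior pair (±0.8, −1.0), and elongated
posterior "trails" of progenitors (components at (±1.2, −1.2) with AP
variance 0.6 vs ML 0.12). Per-animal point counts are drawn from
configurable ranges (1–3 ectopic eyes; progenitor counts as configured) —
the count distribution is this package's choice, as only the spatial
distributions matter for the mapping. Each animal gets a random similarity
pose (inter-eye distance 80–160 px, uniform orientation, y-down handedness;
with `mirror` half the animals get the opposite handedness), and the exact
eye/anterior landmarks plus embedded pixel points are emitted. Round-
tripping through registration recovers the truth to ~1e-15, so the
generator doubles as the oracle for all mapping tests.

## 5. Problem sizes used in the test suite

Simulation-heavy checks run on a reduced stack geometry — 64×64 px
(32×32 µm) fields, 1 µm slices over 10 µm depth, 13–21 cells per stack —
chosen so the full suite (including 400 two-group replicates of 16 stacks
each for power and type-I calibration) completes in a few minutes on one
CPU while keeping ≥ 3 sampled slices per stack and realistic cell packing.
Per-animal true positive counts vary with a 12% coefficient of variation
around group means of 10 (control) and 15 (treated), i.e. the 1.5× ratio
used in the recovery criteria; at this SNR the pipeline recovers the
correct sign in every replicate and p < 0.05 in ≫ 90%, while identical
groups reject at the nominal 5%.

## 6. Known limitations

* The abundance index is interval-dependent; absolute counts are not
  comparable across different sampling intervals (the sweep compares signs,
  not magnitudes).
* Greedy matching can under-match adversarially crowded point sets (see §2).
* The classical segmenter under-detects grazing-plane nuclei whose in-slice
  cross-section falls below the area filter; the occupancy tests therefore
  bracket counts between "comfortably intersecting" and "any intersection".
* The t-test assumes approximate normality of per-sample totals; counts are
  discrete, which is benign at the simulated effect and sample sizes but
  worth revisiting for very low counts.
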