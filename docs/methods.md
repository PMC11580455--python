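# Methods

This note documents the models, conventions and numerical choices behind
`polefrac`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what is computed, under which assumptions, which
parameters matter, and what the synthetic validation does and does not
demonstrate.

## Coordinate and data conventions

Rasters are `(row, col)`, 0-based, origin top-left.  Labelled masks use
0 for background and positive integers for cells; labels are preserved
exactly on input and need not be consecutive.  Fluorescence images are
single-channel; on disk 16-bit TIFF, in memory float64 (the synthetic
generator returns float64, and quantisation to uint16 happens only when
writing).  Trajectories are tables of `(cell, time_s, x_um, y_um)` with a
constant frame interval.  Connectivity is 8-connected throughout, the
standard choice for thin, possibly diagonal pixel structures.

## Cell geometry

Each cell's medial axis is computed by skeletonising the cell mask
(scikit-image thinning), taking the longest geodesic path through the
skeleton (double-sweep Dijkstra with Euclidean step weights, which prunes
side branches), trimming half a cell width from each end to remove the
short diagonal "hooks" thinning leaves near rounded ends, and extending
both ends along their local tangent in 0.25-px steps until they exit the
mask.  The two final endpoints are the pole tips.  Cell width is estimated
as twice the mean Euclidean distance transform along the skeleton path
(computed on a 1-px padded raster so the transform sees the cell
boundary).  Every cell pixel receives an arc coordinate — the arc length,
from tip A, of its nearest axis vertex.

Cells are excluded, with a diagnostic, when they have fewer than 9 pixels,
produce a degenerate skeleton, or have an axis shorter than twice their
width (round or amorphous objects for which "poles" are undefined); labels
split into several connected components are rejected as broken
segmentations; cells touching the image border are excluded by default
because their truncated fluorescence would bias the polar fractions.

**Polar caps.** The analysis needs a region within which clusters count as
"polar".  The cap is defined as an axis fraction: cap A is
`arc ≤ cap_extent · L`, cap B is `arc ≥ (1 − cap_extent) · L`, with
`cap_extent = 1/6` by default — approximately the hemispherical end caps of
a rod six times longer than wide.  Because the literature pipelines do not
publish this boundary, `cap_extent` is an explicit first-class parameter
rather than a constant.  `cap_extent = 0` yields empty caps; values ≥ 0.5
are rejected (caps would overlap).

Rotation of a scene by 90° rotates axes and caps correspondingly at
geometric precision (tips map to within ~1 px, caps overlap strongly), but
not bit-for-bit: raster thinning is not exactly rotation-equivariant.

## Fluorescence quantification

All statistics are computed on background-subtracted intensities; the
background is the median of the non-cell pixels.  Without subtraction,
"percentage of total fluorescence" would depend on the camera offset.

**Cytoplasmic reference.** The mean and SD of cytoplasmic fluorescence are
computed over the mid-cell pixels (cell minus both caps).  This breaks the
circularity of defining cytoplasm as "whatever is not in a cluster", is
single-pass and deterministic, and is unbiased when clusters are polar —
the working assumption of the whole analysis.  The SD uses the population
convention (divisor *n*); with hundreds of mid-cell pixels the distinction
from *n − 1* is negligible, but the convention is fixed and documented.

**Cluster detection.** Within each cap, seed pixels are those *strictly*
above `mean + k_sd · SD` (defaults `k_sd = 2`); 8-connected components of
seeds are kept when they contain at least `min_size = 3` pixels and their
component mean is at least the same threshold.  The criterion is applied
both per pixel (to delimit candidate components) and per component (the component-level
acceptance rule); for components built from strictly suprathreshold
pixels the component-mean test is implied, but it is kept explicit so the
two knobs can be varied independently.  The strict inequality matters in
the degenerate uniform-cell case (SD = 0): no pixel exceeds the threshold
and no cluster is reported, rather than the entire cap.

With independent pixel noise, roughly 2.3% of cap pixels exceed a 2-SD
threshold by chance, so a few percent of genuinely diffuse cells acquire a
false ≥ 3-px cluster.  This is a structural property of the threshold rule,
not of this implementation; it inflates the unipolar count of diffuse
populations by ~3–7% in the synthetic validation and should be kept in
mind when interpreting small "polar" percentages in dim strains.

**Pole assignment, ω and categories.** Cluster fluorescence is summed per
cap; the cap with the larger total is pole 1 (exact ties break to cap A,
the pole at arc 0, for determinism).  For cells with at least one cluster,
`ω = (pole1 − pole2) / (pole1 + pole2)`, which is scale-free and lies in
[0, 1].  Categories: unipolar (ω > 0.9), bipolar asymmetric
(0.9 ≥ ω ≥ 0.2), bipolar symmetric (ω < 0.2), diffuse (no cluster).  The
boundary values belong to the bipolar-asymmetric bin by the stated inequalities
(unipolar requires strictly greater, symmetric strictly smaller).  "No polar signal" is implemented as "no
component satisfying both detection rules" (not "no suprathreshold
pixel").

**Cluster totals: raw vs cytoplasm-subtracted.** By default the cluster
total is the raw background-subtracted sum over cluster pixels, matching
the "total fluorescence at the pole" convention.  The raw total includes
the diffuse signal under the cluster footprint and therefore exceeds the
spot-only signal by approximately
`(cluster area / cell area) × diffuse fraction` — a few percentage points
under typical conditions.  With `subtract_cytoplasm=True` the local
cytoplasmic level (`cytoplasmic mean × cluster area`) is removed, giving
an approximately unbiased estimator of the spot-only fraction; this is the
estimator used when validating recovery of the generator's ground-truth
fractions, which are spot-only by construction.  ω is a ratio and is far
less sensitive to the choice.

Per-cell output percentages satisfy
`pole1_pct + pole2_pct + cytoplasmic_pct = 100` to machine precision, and
multiplying the background-subtracted image by any positive constant
changes no percentage, ω or category (thresholds and totals scale
together; the strict seed inequality is preserved).

## Population aggregation

Summaries (category percentages; mean polar and cytoplasmic percentages
over *all* cells, clustered or not) are computed per replicate, and pooled
as the unweighted mean of replicate means — replicates are the experimental
unit, and this matches the convention of reporting "the mean of all
experiments".  Cell-weighted pooling is available (`pooling="cells"`).
The scatter table (pole-2% against pole-1%, clustered cells only) always
satisfies `pole1_pct ≥ pole2_pct`, so points fall on one side of the
symmetry line.

The significance test is the two-tailed Student's t-test for samples with
equal variances (pooled variance, `n_a + n_b − 2` df).  Whether the test
units should be single cells or replicate means is a study-design choice;
both are possible here (pass cells, or replicate means, as the samples).
Zero pooled variance with equal means returns `(t, p) = (0, 1)`; with
unequal means the statistic is undefined and an error is raised rather
than returning an infinity.

## Motility metrics

Speeds are per-interval Euclidean displacements converted to µm/min; the
requested interval must match the trajectory (20 s and 30 s are the
standard assay settings; a mismatch is treated as a configuration error).
Reversal detection is deliberately simple and fully parameterized, because
published assays state the reported quantity (reversals per cell per
15 min) but not the detection rule: steps shorter than `min_step`
(default 0.03 µm, half a camera pixel) are ignored; a reversal is counted
when the direction of the remaining displacement turns by more than
`angle_threshold = 120°` relative to the current heading and the turned
direction persists for 2 intervals.  The persistence requirement rejects
single-frame noise excursions while a true 180° flip always passes; a flip
on the final step, where no confirmation step exists, is accepted.  With
10% positional noise the detector recovers programmed counts exactly in
> 95% of synthetic tracks.  Counts are normalised to a 15-min window
(`count × window / duration`) when tracks are shorter or longer than the
window.

"Only cells that moved for the entire recording period" is operationalized
as *every* interval displacement ≥ `min_step` — the only frame-local,
deterministic reading; a cell pausing for a single frame is excluded.

## Synthetic data generator

The generator emulates the statistical structure the quantification
assumes, with exact ground truth:

* **Geometry** — spherocylinders (capsules) rasterized at
  `pixel_size = 0.06 µm/px` (typical 100× objective / sCMOS sensor),
  width 0.5 µm, length uniform in 5–7 µm, random or fixed orientation,
  placed by rejection sampling with a ≥ 2-px gap between cells and a clear
  border margin (the analysis operates on separated, non-border cells).
  Placement failure after bounded retries raises an error carrying the
  number of cells placed.
* **Fluorescence** — per cell, a total intensity (default 50 000 counts)
  split into two polar Gaussian spots (`cluster_sigma = 1.3 px`, a
  diffraction-limited PSF σ of ~80 nm at this pixel size) anchored at the
  two spherocylinder cap centres, plus a uniform diffuse remainder.  Spot
  profiles are renormalized over their in-cell support, so the integrated
  in-cell spot flux equals *exactly* `fraction × total_intensity` and
  noise-free conservation is exact rather than approximate.  Which
  physical pole receives the larger fraction is randomized.
* **Noise** — Poisson shot noise on expected counts (background default
  100) plus additive Gaussian read noise (default SD 5), both optional and
  driven by the scene seed.  Camera-level parameters (background, noise)
  are scene-wide and taken from the first cell's localization spec.
* **Truth** — per cell: exact pole fractions, true ω, and the true
  category computed with the *same* binning function the pipeline uses
  (cells with zero polar fraction are diffuse), plus spot anchors and pole
  tip coordinates.  Truth and pipeline output are therefore directly
  comparable.
* **Trajectories** — constant speed, straight-line motion with programmed
  180° flips applied in continuous time, sampled at the frame interval,
  with optional Gaussian positional noise added after sampling.  The truth
  table stores the programmed reversal count regardless of noise.  A
  reversal programmed mid-interval produces a shortened displacement in
  that frame (the cell doubles back); validation cohorts therefore program
  reversals on frame boundaries, where a flip registers cleanly.

What the generator does *not* emulate: curved cells, cell-to-cell contact,
uneven illumination, out-of-focus light, photobleaching, pixel-correlated
noise, and segmentation errors beyond what the geometry checks reject.
Passing the synthetic validation therefore demonstrates correctness of the
measurement logic under the model's assumptions, not robustness to every
artefact of real microscopy; the raw-vs-subtracted cluster total and the
cap extent remain the user's responsibility to match to their optical
setup.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use scenes of up to 500 cells
(mixed conditions, 2600² px) and 200 cells per localization condition
(1700² px), 100-track motility cohorts, a 10⁴-pair grid for the ω bins,
and 50 random cells for the cluster-detection oracle — sizes chosen so the
entire validation runs in well under a minute on one CPU while keeping
per-condition sampling error far below the tolerances being checked.

## Known limitations

* The medial axis assumes near-straight rods; strongly curved or branched
  cells are excluded by the aspect check rather than traced.
* The 2-SD cluster rule has a built-in false-positive rate on diffuse
  cells (see above); comparisons of "percent diffuse" across strains are
  robust, absolute values near 100% are slightly underestimated.
* Reversal detection reports direction changes of the centroid track; it
  does not verify that movement resumed along the cell's long axis, which
  would require the image series.
* The t-test helper implements exactly the equal-variance test; it does
  not choose units (cells vs replicates) for the user and applies no
  multiple-testing correction.
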