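# Methods

This note documents the models, defaults and numerical choices behind
`morphoscreen`, what the synthetic-data generators emulate, and the known
limitations of both.

## Data model

A `FeatureTable` holds one row per segmented cell with metadata (`cell_id`,
`image_id`, `condition`, `replicate_day`, `timepoint_h`, plus any
`Metadata_*` columns) and real-valued feature columns.  `cell_id` must be
unique within an image, and each image must map to exactly one (condition,
replicate day, timepoint).  Rows containing any non-finite feature value are
dropped at load time and counted in the load report.  The feature set is
data-driven — all numeric non-metadata columns — and is never assumed to
have a fixed size, since per-object exports vary in which measurements are
enabled.  The CellProfiler dialect maps `ImageNumber`/`ObjectNumber` and
`Metadata_Condition`/`Metadata_ReplicateDay`/`Metadata_Timepoint` onto the
plain schema; the delimiter (comma/tab) is detected from the header, decimal
points only.  Floats are parsed with round-trip precision so write→read is
bit-exact.

## Condition dissimilarity

**Z-scoring** pools across all cells of all conditions jointly (population
SD, ddof 0), so every condition is measured against the same experiment-wide
scale.  A per-batch variant would change the meaning of distances between
batches and is deliberately not the default.  Zero-variance features are
dropped (they carry no distributional signal) and listed in the run
manifest.  A side effect worth knowing: when one condition carries a large
shift, it inflates the pooled SD, so the realized distance under-states the
nominal per-condition effect size; rankings are unaffected.

**EMD.** For two 1-D samples the first Wasserstein distance is computed
exactly as the integral of |F_a − F_b| over the merged support (equivalently
the L1 distance of quantile functions), handling unequal sample sizes with
uniform weights and no binning — binning would introduce a free parameter
with no principled default.  Two identities make the implementation
testable: W(x, x + c) = |c| for any constant c, and for equal-size samples
W equals the minimum-cost perfect matching of order statistics.  The test
suite checks the implementation against a brute-force permutation oracle
(n ≤ 8), an exact linear-program transport oracle (unequal sizes), and
scipy's independent implementation.

**Aggregation.** D_ab = √(Σ_j W_j²) over all surviving features — no
significance pre-filter, since a filtered distance would depend on the
screening threshold.  The Euclidean norm of per-feature metrics is itself a
metric; symmetry, zero diagonal and the triangle inequality are asserted in
tests on random tables.  Conditions with fewer than `min_cells` (default 50)
cells are excluded with a warning: below that, per-feature EMDs are
dominated by sampling noise (the EMD between two n-samples of the same
distribution scales like n^(−1/2)).

**Embedding.** Default is classical (Torgerson) MDS: double-centre −D²/2
and take the top-2 eigenpairs.  It is deterministic, exact for
plane-embeddable configurations, and needs no iteration; a sign convention
(largest-magnitude coordinate positive per axis) makes output stable across
runs.  SMACOF (metric stress majorization, seeded) is available when D is
strongly non-Euclidean.  Reported stress is Kruskal's normalized stress-1.

**Screening.** Cells within an image are correlated, so the per-feature
Kruskal–Wallis test runs on per-image means (the image is the independent
unit), with midrank tie correction and a chi-square reference (groups − 1
df).  Benjamini–Hochberg adjustment is applied across features and both raw
p and adjusted q are reported, with significance called at q < 0.05 by
default.  Fully tied data yields H = 0, p = 1 rather than an error.

**Clustering** of conditions uses Ward-D2 linkage on Euclidean distances
(scipy), returning the merge tree and dendrogram leaf order for heatmaps.

## Image-level QC

Within each (condition, timepoint) group, per-image object counts and
per-image feature medians are scored with a robust z: (x − median) /
(1.4826·MAD), falling back to IQR/1.349 when the MAD is zero, and to
flagging only exact departures from the median when both vanish.  An image
is flagged when |z| exceeds 3.5 (the conventional outlier-labelling cut) on
the count or on any feature median; thresholds are configurable.  Groups
with fewer than three images are passed untouched with a warning, and a
`min_images_kept` guard (default 2) keeps the least-outlying flagged images
rather than emptying a condition.  Limitation: with the typical 3–7 images
per condition the MAD is estimated from very few values and the per-feature
false-flag probability is non-negligible for continuous data; the original
screening workflow resolved this with manual review, which has no
algorithmic equivalent — here every flag is retained in an audit report
instead, and thresholds can be raised for small designs.

## Masks and measurements

Matching uses the containment fraction o = |nucleus ∩ cell| / |nucleus|
(denominator: nucleus area), threshold 0.9; each nucleus joins at most one
pair (best cell wins; exact ties go to the lower cell label), multinucleate
cells keep one row per nucleus, and cells without a matched nucleus are
excluded downstream.  Whether an intersection-over-union denominator would
behave differently is moot at 0.9 for nuclei much smaller than cells; the
threshold is exposed.

The cytoplasmic ring of a nucleus is the set of non-nucleus pixels within
Euclidean distance `width_px` (default 15) of it, computed with a single
distance transform; a contested pixel belongs to the nearer nucleus, with
exact ties resolved by the transform's scan order rather than by label
(a measure-zero pixel set).  With a cell mask present, rings are clipped to
the matched cell.  Rings never intersect nucleus pixels by construction.

Shape features per matched cell: area, perimeter (chain-code approximation
with √2 diagonal weighting, via scikit-image), equivalent diameter,
eccentricity, form factor 4πA/P², max and mean centroid-to-boundary radius,
nucleus area and nucleus/cell area ratio; per channel, mean/median/
integrated intensity over nucleus, ring and cell.  On rasterized primitives
these converge to the closed forms as O(1/r).

Illumination correction divides by a heavy Gaussian background estimate and
rescales to preserve the global mean.  The smoothing scale should be large
relative to cell size but small relative to the image; near borders the
estimate is biased by edge padding, so a scale above ~1/6 of the image width
leaves visible residuals.

## Reporter, stain and viability assays

KTR activity per cell is r = median ring intensity / median nucleus
intensity (medians, not means, for robustness inside compartments); the
per-image statistic is the mean of per-cell calibrated activities.
Calibration (r_min, r_max) is external by design — the floor is the
fully-inhibited-kinase ratio and the ceiling the growth-factor-saturated
ratio from a reference experiment — and activities are clipped to [0, 1]
with clip counts logged.  A percentile-based self-calibration (2.5th/97.5th
of observed ratios) is provided for experiments without a reference, with
the caveat that its zero and one are relative to the observed data only.
Cells with zero nucleus median cannot define a ratio and are dropped with a
reason code.  Because r is an intensity ratio within one image, activities
are exactly invariant to global detector gain.

Stain quantification divides each cell's mean and integrated intensity by
the control population mean of the same statistic.  Viability maps a plate's
raw absorbance shifts affinely so blank wells read 0 % and the vehicle
control mean reads 100 %.

## Differentiation scoring

Cell regions are thinned to a 1-px skeleton (scikit-image `skeletonize`);
length L sums the 8-neighbour graph edges — 1 per orthogonal edge, √2 per
diagonal, with diagonal chords suppressed when their endpoints already share
an orthogonal skeleton neighbour, so staircase corners are not
double-counted.  Branch points are skeleton pixels of degree ≥ 3.  A cell is
differentiated iff L > τ (default 100 px, strict).  L is exactly
translation-invariant; thinning is only approximately equivariant under 90°
rotation (≈2 % length variation on elongated regions), which the tests
acknowledge.  When only nuclei are segmented, cell regions are recovered by
Otsu-thresholding a cytoplasmic reporter channel and growing watershed
regions from nucleus seeds (8-connectivity, so 1-px diagonal neurites are
traversed).

## Proliferation metrics

Counts are per-image matched-cell counts averaged per (condition, day,
timepoint); single-image groups are flagged.  Day effects are removed by
normalizing to the same-day control (cells grown without a medium change)
*within* each day before averaging across days — multiplying all counts of
one day by any constant provably cancels.  The growth fold is
g = N(72 h)/N(24 h) per well.  The heat-map scale is fixed on the log scale
as ĝ = log2(g) / mean over conditions of log2(g): ĝ = 0 exactly when g = 1
(no growth) and mean ĝ = 1 (average growth for that cell line).  Other maps
satisfy the same two anchors; the log2 form is this package's choice and is
reported as such.  It is undefined when the mean log2 growth is zero, which
is raised as an error rather than silently rescaled.

## Synthetic generators

The generators emulate the statistical structure of the study design — many
conditions, 3–4 images per condition, 50–250 cells per image, 24 h/72 h
counting with a same-day control — not the optics of microscopy (no PSF,
no bright-field texture, no segmentation errors).

* **Feature tables.** Features cycle through three documented families:
  sizes lognormal (μ = ln 300, σ = 0.4), intensities normal (100, 15), shape
  ratios beta (2, 5) — sizes and intensities are right-skewed in real data,
  shape ratios bounded.  Condition effects transform affected features as
  x ↦ m + k(x − m) + d·s with (m, s) the family's closed-form mean/SD, so
  the realized standardized mean difference equals the nominal d up to
  sampling error (verified within 0.15 SD at n = 1000).
* **Two-compartment cells.** Concentric nucleus (r = 7 px) and cytoplasm
  (r = 16 px) disks placed without overlap by rejection sampling, reporter
  intensity constant per compartment (defaults 100/50) plus optional
  Gaussian noise.  The truth table carries the constructed C/N ratio.
* **Neurites.** A soma disk plus a one-pixel persistent random walk of known
  √2-weighted path length; each cell lives in a private 120-px box so
  neurites of different cells never touch.  Short/long lengths are drawn
  from gamma distributions (means 19 px and 150 px — the former matching the
  typical undifferentiated skeleton length, the latter comfortably above the
  100-px cut) truncated at the cut so class membership is exact by
  construction.  Measured skeleton lengths carry a small positive bias from
  the soma and a small negative bias from end-pixel thinning; correlation
  with truth exceeds 0.99 in practice.
* **Growth counts.** Multiplicative lognormal noise with unit mean and a
  given CV, applied independently to each count; cv = 0 reproduces folds
  exactly.

All generators are deterministic given an explicit integer seed and share no
global state.  Passing tests on these data demonstrates the *statistics* are
implemented correctly; they say nothing about segmentation quality, focus
artefacts or optical effects in real images, which enter upstream of this
package.

## Problem sizes

Defaults used in the test suite and the acceptance script: effect-size
recovery at 1000 cells/condition over 50 features (20 affected); reporter
recovery on 50-cell fields at noise SD ∈ {0, 2, 5}; differentiation on 500
cells at a 30 % long fraction; growth recovery with 3 replicate days at 10 %
CV; null calibration of the screen with 1000 simulations of 3 × 8 image
means.  These sizes give stable recovery (sampling error comfortably inside
the asserted tolerances) while keeping the full suite fast enough to run on
every change.
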