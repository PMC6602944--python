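# Methods

## Repeatability model

Each feature value measured on subject *i* at timepoint *j* ∈ {test,
retest} is modelled by the one-way random-effects ANOVA

x_ij = μ + b_i + e_ij,  b_i ~ N(0, σ_b²),  e_ij ~ N(0, σ_w²),

with no systematic difference between the two scans (both are acquired
under unchanged conditions, so scan order carries no fixed effect; any
segmentation inconsistency is absorbed into the within-subject term).
With BMS and WMS the between- and within-subjects mean squares of this
ANOVA (k = 2 replicates), the single-measurement intraclass correlation
is

ICC(1,1) = (BMS − WMS) / (BMS + WMS),

an estimate of σ_b² / (σ_b² + σ_w²).  The estimator's natural range is
[−1, 1]; negative estimates are reported, not truncated, because
truncation at zero would bias rank-based summaries (rank histograms,
top-k selections) toward ties.

**Confidence intervals.**  The (1−α) two-sided interval uses the
Shrout–Fleiss F-based construction: with F = BMS/WMS, F_L =
F / F_{1−α/2}(n−1, n) and F_U = F · F_{1−α/2}(n, n−1), the bounds are
(F• − 1)/(F• + 1) for k = 2.  α defaults to 0.1 (a 90 % interval).
Under the normal one-way model this interval is exact; the test suite
verifies ~90 % empirical coverage at a true ICC of 0.7 with n = 15.

**Missing data.**  Features can be undefined on degenerate inputs
(e.g. GLCM Correlation on a constant ROI).  Such values are flagged NaN
at extraction, and subjects with a missing value at either timepoint are
dropped pairwise per feature key, with the retained n recorded.  Keys
where all retained values are identical (BMS = WMS = 0) have no defined
ICC and are reported NaN rather than dropped, so table cardinalities
stay auditable.

## Processing pipeline

The per-configuration order is fixed: **normalize → filter →
discretize → texture matrices → features**.  Normalization precedes
filtering because both normalization schemes are plain affine maps of
the raw image; filtering a normalized image is what the downstream
feature definitions assume.

### Normalization

Two affine schemes, both fitted with the population (divide-by-N) SD:

* *whole_image*: all voxels mapped so the image mean/SD become 300/100,
  putting most intensities in 0–600 for roughly Gaussian histograms;
* *reference_region*: the map is fitted on a designated homogeneous
  reference ROI (muscle-like tissue; low intensity, low variance) so its
  mean/SD become 100/10, then applied to every voxel.  The smaller
  targets keep the whole image in a reasonable range, since the
  reference occupies the low end of the intensity scale.

No clipping or outlier handling is applied.  Constant inputs (zero SD)
are rejected as degenerate rather than silently passed through.

### Filter bank

* **LoG** operates in physical space: per-axis Gaussian SD =
  σ_mm / spacing_axis, so the scale is isotropic on anisotropic grids;
  the Laplacian term for each axis is divided by spacing² (units
  1/mm²).  Kernels are analytic Gaussians (and second derivatives)
  sampled at integer offsets, truncated at 4σ, sharing the smoothing
  kernel's normalization; the derivative kernel is mean-corrected to sum
  to zero so constants map exactly to zero.  Boundaries use symmetric
  reflection.
* **Wavelet** sub-bands come from a single-level stationary
  (undecimated) transform, default family `coif1`, symmetric padding of
  odd axes.  Sub-band letters are given per axis in physical (x, y, z)
  order.  Single-slice images use two-letter in-plane sub-bands.
* **Intensity transforms** (square, √|x|, log(|x|+1), eˣ) are linearly
  rescaled so the output's maximum magnitude equals the input's, with
  the original sign restored per voxel.  The transform states the
  contract, not a formula, so the rescaling is the simplest map
  honouring it.  The exponential pre-scales its argument when the input
  magnitude exceeds 20 to avoid float overflow; pre-scaling is monotone,
  and the output is range-restored regardless.

### Discretization and texture matrices

Fixed-bin-width discretization is anchored at the ROI minimum:
level(x) = ⌊(x − min)/w⌋ + 1, computed from ROI intensities only, so
Ng ≤ ⌊range/w⌋ + 1 (128 levels for a range just under 5120 at w = 40).
An alternative convention that aligns bin edges at multiples of w is
exposed as an optional `aligned` mode; the minimum-anchored form is the
default because it makes Ng depend only on the ROI range.

Texture matrices use conventions the source material leaves
unspecified; the choices here are fixed and recorded on the matrix
(`aggregation` tag, `n_directions`):

* GLCM: distance 1 voxel, symmetric accumulation, 13 unique directions
  in 3D / 4 in-plane directions in 2D, counts merged across directions
  (and slices) **before** normalization, one matrix per configuration.
* GLRLM: maximal same-level runs per direction, merged the same way;
  Σ r(i,l)·l = |ROI| · n_directions.  RunPercentage is therefore
  n_runs / Σ r(i,l)·l, the per-voxel-per-direction run rate.
* GLSZM: connected components of constant level, 26-connectivity in 3D,
  8-connectivity per slice in 2D; Σ s(i,z)·z = |ROI|.

Merging before feature computation (rather than per-direction feature
averaging) was chosen for determinism and testability: each
configuration yields exactly one matrix, checkable against a
brute-force enumeration oracle.

### Feature roster

Five classes: first-order (9 features), shape (8), GLCM (7), GLRLM (5),
GLSZM (5).  Excluded by construction: Compactness1/2 and
SphericalDisproportion (deterministic functions of Sphericity),
Flatness and LeastAxisLength (meaningless for single-slice regions),
SumAverage (≡ 2·JointAverage for symmetric matrices; the identity is
kept as an internal cross-check), Homogeneity1/2 (duplicates of the
inverse-difference statistics).

Conventions: percentiles interpolate linearly between order statistics;
Kurtosis is non-excess (normal ⇒ 3); Variance/Skewness/Kurtosis use
population moments; first-order Entropy is computed on the discretized
levels, log₂, with 0·log 0 = 0.  Volume is voxel-count volume (count ×
voxel volume) rather than mesh volume — ICC is scale-invariant, so the
distinction does not affect repeatability comparisons, only absolute
values.  Surface area counts exposed voxel faces; diameters are
measured between voxel centres; axis lengths are 4·√λ of the
physical-coordinate covariance eigenvalues.

Shape features depend only on (mask, ROI) and are identical across the
whole filter bank; they are still emitted under every configuration
fingerprint so downstream tables stay rectangular.

## Synthetic phantom cohorts

The generator emulates the variance structure of a test–retest MR
cohort, not MR physics.  Geometry: an ellipsoidal gland with a
posterior peripheral-zone band on a 16×48×48 grid at 1×1×3 mm spacing
(≈48 mm cube), a spherical lesion (radius 6 ± 1 mm, centre jittered ±3
mm per subject) inside the peripheral zone, and a homogeneous anterior
muscle-like reference cylinder.

Per subject (shared by both timepoints): a global intensity shift
b ~ N(0, σ_b²) with σ_b = 20 by default, and a smoothed-white-noise
texture field (correlation length 2 mm, SD 10 in gland/tumor tissue, 2
in the muscle reference — the reference is deliberately more
homogeneous).  Per scan (independent between timepoints): white noise
with σ_w = 15, a global gain 1 + N(0, 0.05²) and offset N(0, 10²) to
exercise normalization, and with probability 0.3 a one-voxel dilation
or erosion of the tumor contour emulating segmentation inconsistency
(erosion never empties the ROI).  Intensity levels (background 50,
gland 220, peripheral zone 260, tumor 180, muscle 80) follow the
qualitative T2-weighted ordering of prostate tissue.  These defaults
are plausible for mildly noisy clinical MR after bias correction; no
published quantification of contour inconsistency exists, so the jitter
magnitude is a free parameter rather than a calibrated one.

Seeding uses one master seed with per-(subject, timepoint) spawned
substreams, so cohorts are bit-reproducible and the first n subjects do
not change when the cohort grows.

**Closed-form ground truth.**  With gain/offset fixed, the ROI-mean
feature of one scan is μ + b + mean(noise), giving

ICC_theory = σ_b² / (σ_b² + σ_w²/N),

with N the expected ROI voxel count of the nominal anatomy.  The
formula ignores contour jitter and assumes the texture field's ROI-mean
contribution is negligible (exact at texture SD 0); parameter-recovery
simulations therefore disable texture, jitter and geometry jitter.
`calibrate_sigma_b` inverts the formula to hit a target ICC.

**What the phantoms do not emulate** — and hence what passing tests do
not show about real data: no bias fields, k-space artifacts, geometric
distortion, partial-volume effects, scanner or protocol differences, no
realistic tissue boundaries or heterogeneous lesions, and contour
errors far simpler than human inter-session variability.  Passing the
phantom suite shows the *estimator and pipeline* behave correctly under
a known variance structure, not that any particular feature is
repeatable in clinical images.

## Summary analyses

All summaries are deterministic functions of the per-feature ICC table
(CSV is the contract; plots are optional):

* **Volume reference** per (ROI, image type) — the in-study threshold.
* **Bin-width range** (max − min ICC over the four widths per
  feature × filter) and **rank histogram** (widths ranked per key by
  ICC descending; ties share the better rank; each column sums to the
  key count).
* **Top-3 per class**: "best configuration" is the maximum ICC over the
  filter grid at the reporting bin width 15 — the grid's middle-rank
  width; ties break lexicographically by feature name so reports are
  reproducible.
* **Filter frequency above reference**: a feature counts under *every*
  filter beating the reference, so per-filter counts can exceed the
  distinct-feature total summed, but each count is bounded by it.
* **Normalization delta**: paired per-feature ICC differences between
  two normalization modes, plus the union of both modes' top-3 sets
  (up to 6 features per class).

## Problem sizes and numerical tolerances

The bundled test and acceptance runs use scaled-down cohorts chosen to
keep the full suite fast while leaving every estimate identifiable:
8×26×26 phantom grids for simulation studies (tumor ≈ 290 voxels),
500 Monte-Carlo cohorts of 15 subjects for parameter recovery, 200
random ≤6³ grids for texture-matrix oracles, and a 5-subject reduced
grid (4 filters × 2 bin widths) for the end-to-end demo.  Exact
contracts (normalization targets, ANOVA oracles) are asserted at
1e−6–1e−10; stochastic checks at Monte-Carlo precision (±0.05 on a mean
ICC, ±4 percentage points on CI coverage).  LoG agreement with the
brute-force convolution oracle is asserted at 1e−6 relative to the peak
response.

## Known limitations

* No N4 bias-field correction, DICOM ingestion, registration, or
  multi-reader analysis; inputs are assumed co-registered and
  bias-corrected.
* Texture conventions (direction set, distance, symmetry, merging,
  connectivity) are fixed choices, documented above; other toolkits'
  per-direction-averaged features will differ numerically.
* The exponential transform's overflow guard changes its values for
  inputs with magnitude above 20 (monotonically); only the rank
  structure and range contract are preserved there.
* ICC(1,1) assumes no systematic test→retest shift; a scanner drift
  common to all subjects would be misattributed to within-subject
  variance.
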