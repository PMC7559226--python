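# Methods

## Problem setting

The unit of analysis is an 8-bit grayscale patch cropped from a TRUS
frame along a biopsy-needle track, carrying a binary histology label
(`positive` = cancer found in the core, `negative` = clean core) and a
case (patient) identifier.  Labels are per-patch, not per-pixel, and a
positive patch may contain normal tissue; a negative patch is reliably
normal.  Because several patches come from one patient, all evaluation
splits are made at case level: image-level splitting would let a
patient's texture appear on both sides of a split and inflate accuracy.

## Optical-density preprocessing

`OD_ij = ln(I_ij / I_o)`, `I_o` = arithmetic mean of the (unclamped)
patch intensities, followed by an affine remap of `[min OD, max OD]`
onto `[0, 255]` with half-to-even rounding.  Conventions where the
definition is silent:

* **Log base**: natural log.  Any fixed base rescales OD by a constant,
  which the affine remap cancels, so the choice is immaterial
  downstream.
* **Zero pixels**: `ln 0` is undefined; intensities are clamped to
  `clamp_floor` (default 1, the smallest positive 8-bit value) before
  the log.  The mean `I_o` uses the raw values.  An all-zero patch is an
  error.
* **Scope of `I_o`**: the mean of the ROI being transformed, not of a
  surrounding frame (overridable by preprocessing a larger crop first).
* **Constant patch**: OD is identically 0; the remap sends a constant
  grid to all-zeros by convention.

The composed transform is exactly invariant under global multiplicative
gain (`ln(cI/cI_o) = ln(I/I_o)`) and monotone in intensity.

## LBP

Neighbour i of a pixel sits at angle `2πi/N` from the +x axis,
counter-clockwise, at radius R (defaults N = 8, R = 1), sampled by
bilinear interpolation; bit i (weight `2^i`) is set iff the sample is
`≥` the centre value.  Ties count as 1, with no tolerance: an
interpolated sample exactly equal to the centre sets the bit.  Border
pixels within `ceil(R)` of the edge are dropped rather than padded, so
the code image is smaller than the input and no neighbours are
fabricated.

* **Bit order / start angle** are conventions; the rotation-invariant
  (`ri`) mapping — minimum over all N circular bit-rotations — makes
  them immaterial, and is the default.  `raw` (2^N codes) and `riu2`
  (uniform patterns to their popcount, all others to one bin, N + 2
  bins) are selectable.
* **Numerical care**: sampling offsets are rounded to 9 decimals so
  positions related by 90° rotation are bit-identical floats, and the
  bilinear interpolation uses the two-stage lerp form, which is exact on
  constant patches.  Consequently a constant image yields code
  `2^N − 1` everywhere exactly, and `ri` histograms are exactly
  invariant under 90°/180°/270° rotation.
* Codes are exactly invariant under positive affine intensity maps in
  real arithmetic; with floats this holds to the last bit except on
  exact interpolation ties, which have measure zero for generic images.

Pooling is a normalized histogram over the mapping's bin range
(36 bins for `ri`, N = 8).

## GMRF

Model: each pixel of the standardized patch (zero mean, unit variance)
is conditionally Gaussian given its neighbours with mean
`Σ_r θ_r (x_{s+r} + x_{s−r})` and variance ν.  Symmetric offset pairs:
order 1 = {(0,1), (1,0)}, order 2 (default) adds {(1,1), (1,−1)} — five
features `[θ_01, θ_10, θ_11, θ_1−1, ν]`.  Because the conditional mean
is exactly linear in the neighbour sums, least squares over interior
pixels is consistent for θ; ν is the mean squared residual.
Standardization makes θ unit-free and ν comparable across patches.  A
constant patch (zero variance) and singular normal equations are
errors.

**Synthesis** draws realizations on the torus by spectral sampling with
power `ν / (1 − 2 Σ_r θ_r cos(ω·r))`.  The DC component is fixed at 0
(zero-mean convention), so stationarity is required — and checked, with
the violating frequency reported — only at nonzero DFT frequencies.
This admits intrinsic fields with `Σθ_r = 1/2` exactly, such as
θ = (0.20, 0.20, 0.05, 0.05), which sits on the boundary; estimation
remains well behaved there (max per-coefficient error < 0.01 at 256²
over 10 seeds, against a ±0.03 working tolerance).  With θ = 0 the
model collapses to white noise of variance exactly ν.

## Fusion

The default `lbp_then_gmrf` scheme extracts the LBP feature image first
and then fits the GMRF *to the raw LBP code grid* treated as a
real-valued field, concatenating the `ri` histogram (36) with those
parameters (5) into a 41-vector.  Two readings of "combine LBP and GMRF
linearly" coexist — fit the GMRF on the LBP image, or concatenate
independent blocks — and this default honours both (concatenation *is*
a linear combination of feature blocks).  The raw code grid rather than
the `ri` grid is used for the GMRF fit because orbit bins are unordered
labels while raw codes at least form a numeric field.
`concat_lbp_gmrf` (LBP histogram + GMRF of the intensity image) and
`concat_all` are selectable; when GMRF features are used alone they are
computed on the preprocessed intensity image.

## Classifiers

All four run on features standardized by the training fold's mean/sd
(stored in the fitted model; never fit on test data):

| kind | backing implementation | fixed settings |
|------|------------------------|----------------|
| svm  | RBF-kernel SVC | γ = 1/(d·var(X)), C = 1; zero discriminant → negative |
| knn  | KNeighborsClassifier | k = 5 |
| dt   | DecisionTreeClassifier | min leaf 2; the C4.5 confidence-factor 0.25 pruning control has no analogue here and maps to "no additional pruning" |
| rf   | RandomForestClassifier | 500 trees, mtry = 61 capped at the feature dimension with a warning (61 > 41 for the default fused vector) |

All are deterministic given the spec's seed.  Predictions use the sign
of the SVM discriminant directly; no probability calibration.

## Evaluation

ACC, SEN and SPEC are percentages kept at full precision internally and
rounded to 2 dp only for display; an empty denominator yields NaN
("NA").  ACC always lies between SEN and SPEC (prevalence-weighted
mean).  k-fold CV is stratified by class at case level (falling back to
an unstratified case-level split when a class has fewer cases than
folds, e.g. leave-one-case-out); the headline CV metrics are unweighted
means over folds, with pooled confusion counts reported alongside.
Every fold asserts that no case id occurs in both train and test.

## Synthetic phantoms

Each patch is `clip(μ·exp(σ·G)·S_L, 0, 255)` rounded to uint8, where G
is a unit-variance GMRF field with the class's θ, σ is the
log-echogenicity texture amplitude, and `S_L ~ Gamma(L, 1/L)` is
unit-mean multiplicative speckle.  Defaults:

* patch 64 × 160 px — the approximate aspect of a biopsy-track strip;
* μ = 120 (mid-gray mean echo level);
* classes θ = (0.05, 0.05, 0, 0) vs (0.25, 0.25, 0, 0) — a 0.2 gap on
  the axial coefficients (`PhantomConfig.two_class(gap)` generalizes);
* σ = 0.3 and L = 8.  L is the *effective* number of looks of
  display-processed B-mode: spatial/frequency compounding and
  persistence averaging raise it well above the fully-developed-speckle
  value L = 1, and L = 8 gives speckle CV ≈ 1/√8 ≈ 0.35, comparable to
  the texture-induced modulation so that a 0.2 coefficient gap is
  reliably separable while identical-class datasets stay at chance;
* 20 cases per class × 5 images = 200 images, with one RNG substream
  per case and per image (cases exchangeable, dataset fully
  deterministic given the master seed).

What the phantoms emulate: two-class textured 8-bit patches with
correlated within-case texture statistics, multiplicative speckle and
case structure.  What they do not: point-spread-function anisotropy,
attenuation with depth, shadowing, scan-conversion interpolation, or
the label noise of positive biopsy strips that contain normal tissue.
Passing the phantom suites therefore demonstrates that the pipeline
machinery is correct and calibrated, not that clinical TRUS patches are
separable at any particular accuracy.

## Problem sizes used in the checks

GMRF recovery uses ten 256×256 fields; the null and separated CV
experiments use 200 images / 40 cases each, 5-fold case-level CV, with
all four classifiers on the null dataset and the SVM on the separated
one.  The null band [35%, 65%] is a generous 95% region for mean CV
accuracy at n = 200 under chance.

## Known limitations

* No automatic needle-track detection: ROIs are supplied in the
  manifest (or the patch is the whole image).
* DICOM is deliberately unsupported; convert to PNG/TIFF first.
* The GMRF estimator assumes stationarity within the patch; strong
  depth gradients should be cropped out or corrected upstream.
* `riu2` with N ≫ 8 and radii ≫ 2 are untested territory; N is capped
  at 16 by the rotation-table implementation.
* Reported phantom accuracies do not transfer to clinical data; they
  characterize the generator's study conditions only.
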