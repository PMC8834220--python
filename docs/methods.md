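# Methods

This note documents the models, estimators and design choices behind
`nirtex`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The calibration problem

A diffuse-reflectance FT-NIR spectrum of an intact grape berry is a vector
of absorbance-like intensities on a fixed wavenumber grid
(12,000–4000 cm⁻¹ at 8 cm⁻¹ spacing, 1001 points, stored in descending
cm⁻¹ as FT-NIR instruments emit it; λ[nm] = 10⁷/ν̃[cm⁻¹]).  The targets are
per-berry reference values: total soluble solids (TSS, °Brix, a
refractometric sugar proxy) and the double-compression texture parameters —
hardness BH (N), springiness BS (mm), cohesiveness BCo (dimensionless), and
the derived gumminess BG = BH·BCo (N) and chewiness BCh = BH·BCo·BS (mJ).
Gumminess and chewiness are mutually exclusive descriptors (semi-solid vs
solid foods); only chewiness is modeled for grape, though the generator
emits both.

The pipeline runs, per response: replicate averaging → pre-treatment
selection → outlier screening → Kennard–Stone split → full-spectrum PLS →
wavelength selection → reduced PLS → (augmented) ANN → evaluation.

## Synthetic study generator

No public berry dataset exists, so the generator is a first-class module:
it defines the study conditions under which every pipeline property is
tested.

**Design.**  3 blocks × 3 bags × 30 berries = 270 berries, 3 face spectra
per berry (810 rows), averaged downstream.  Bags are sampled from a
three-component density mixture ("low/mid/high" ripeness classes at 1.00,
1.04, 1.08 g/mL, equal weights, within-class SD 0.012) mirroring the
densimetric-flotation classes a texture lab would use; the class label is
latent — the pipeline never sees it, which is the point of the exercise.

**Spectra.**  Beer–Lambert additive mixing: each chemical component
(water, sugars, organic acids, pectins) is a sum of Gaussian bands in
wavenumber; band centers sit at the positions reported for grape tissue
(10,526; 6896; 6849; 5128; 5917; 5714; 8333; 10,101; 4424; 4344 cm⁻¹).
Gaussians are the standard synthetic-NIR band shape when only centers are
known.  Component concentrations are linear in a latent ripeness
coordinate r (density rescaled to ≈[0,1]): sugars and pectins rise with r,
water and acids fall.  Per-face noise: multiplicative scatter gain
(SD 0.05), additive offset (SD 0.02), linear baseline slope (SD 0.01),
white noise (SD 0.002, consistent with a 64-scan FT instrument), an extra
per-face gain for berry inhomogeneity (SD 0.01), and a small per-block
additive offset (SD 0.015, switchable) that exercises the
design-discrimination rejection rule during pre-treatment selection.

**Reference links.**  TSS is linear in density
(TSS = 56.25·ρ − 41.75 + ε, ε ~ N(0, 0.3 °Brix)), spanning ≈14.5–19 °Brix —
the harvest-ripe range for a seedless table grape — with noise at the scale
of refractometer repeatability plus biological residual.  The texture
parameters are deliberately *nonlinear* in ripeness: logistic functions of
r with a diameter interaction, e.g.
BS = 1.6 + 0.8·σ((r−0.5)/0.12) + (−0.04 + 0.12·σ)·(d − d̄) + ε.
Because the spectra encode r only linearly, a linear calibration (PLS)
underfits these links while a nonlinear regressor with access to the
diameter has genuine headroom — the situation the ANN stage exists for.
Cohesiveness is generated as 0.24 ± 0.03 with only a ±0.008 predictable
component, so its calibration failure is reproducible as a property rather
than an accident.  BG and BCh are computed from the identities exactly
(float-exact per row).  Diameter ~ N(19, 1.5) mm; weight follows the
spherical volume times density plus noise.

**What it does not emulate:** radiative transfer in turbid tissue (no
physical reflectance model), instrument line-shape or detector drift,
seasonal/vineyard covariance structure, or correlated reference-method
errors.  Passing tests therefore demonstrate the *pipeline's* correctness
and the qualitative linear-vs-nonlinear contrast, not field performance on
real fruit.

## Pre-treatments

SNV standardizes each spectrum to mean 0, SD 1 (sample SD, n−1 — the
chemometrics convention; the choice is invisible downstream of scaling).
MSC regresses each spectrum on a reference (training-set column mean by
default) and removes the fitted intercept/slope.  Both provably remove any
per-row affine distortion of a common underlying spectrum.  Savitzky–Golay
uses `scipy.signal.savgol_filter` (window 15, polyorder 2 by default;
derivative scaled per cm⁻¹; polynomial edge interpolation); derivative and
smoothing are one convolution, with a separate derivative-then-smooth chain
available since either ordering is defensible.  Min-max and mean-center
learn constants from the training partition only and never re-estimate on
apply.

**Pre-treatment selection** ranks candidate chains by PC1+PC2 cumulative
variance and flags chains whose first-two-PC scores separate the field
blocks (mean silhouette > 0.25): a pre-treatment that reveals the sampling
design rather than the chemistry would bias the calibration toward field
effects.  Per-response defaults are pinned: SNV + mean-center for
TSS/BS/BCh/BCo, mean-center for BH.

## Outlier screening and critical limits

Screening must precede the split, so it runs on all berries.  Two screens
are combined by union (with per-sample provenance logged):

1. **Mahalanobis** on PCA scores of the pre-treated spectra, with k chosen
   as the smallest PC count reaching 95% cumulative variance (numerically
   null PCs dropped); flag when D² > χ²ₖ(1−α), α = 0.01.
2. **PLS residual distances**, from a screening fit at a fixed moderate
   component count (5 by default; the final models select A by LOO-CV):
   score distance h (leverage; with unit-norm
   training scores, var per component is 1/(n−1) and the training mean of h
   is A(n−1)/n) and orthogonal distance q (squared X-residual norm).  Each
   distance is modeled as u₀·χ²_N/N.  *Robust* estimation matches the
   median and IQR to the corresponding χ² quantile ratio (N searched over
   1…250), making the limits insensitive to the outliers being hunted; it
   is used for screening.  *Data-driven* estimation matches moments
   (u₀ = mean, N = round(2·mean²/var)) and is computed for the final model.
   Limit: u₀·χ²_N(1−α)/N at α = 0.01 for removal.

Removal is one-shot, not iterated.  A degenerate distance distribution
(zero IQR or variance) raises rather than silently passing.

## Split, scaling and leakage

The Kennard–Stone maximin algorithm picks round(0.8·n) calibration samples
(farthest pair first, then maximize the minimum distance to the selected
set; ties break to the lowest original index, making the split
deterministic and permutation-equivariant).  Distances are computed on
all-row min-max-normalized pre-treated data — a metric choice that involves
no response values.  Every *model-stage* constant (pre-treatment constants,
min-max ranges, selection, jack-knife inference, network weights) is then
refit on the training rows only; an audit test perturbs a test row and
asserts all fitted constants are bit-identical.  A `scaler_fit: all`
switch reproduces the normalize-before-split variant, but train-only
fitting is the default because fitting on all rows leaks test information.

## PLS, cross-validation, jack-knife

SIMPLS (single-response): weight vectors come from the deflated
cross-product vector s = X₀ᵀy₀, deflating s against an orthonormal basis of
the X-loadings; scores are orthonormal, β = Rq, and at full rank the fit
equals least squares (for PLS1 the fitted subspace coincides with the
NIPALS Krylov space — both facts are used as independent oracles in the
tests).  Requests beyond the effective rank truncate with a warning.
Component selection: leave-one-out RMSECV over A = 1…A_max (12 by default,
capped at n−2), global minimum with first-index tie-break; a
one-standard-error rule is available.  The LOO loop reuses one A_max fit
per left-out sample and reads predictions off the coefficient path, which
is arithmetically identical to naive refitting.

Jack-knife inference at the selected A: delete-one segments by default
(k-segment supported), SE² = (m−1)/m·Σ(β₍ᵢ₎−β̄)², t = β̂/SE with df = m−1,
two-sided t p-values; SE = 0 maps to p = 0 for a nonzero coefficient and
p = 1 otherwise.  p-values are scale-free in y.  No multiple-testing
correction is applied across wavenumbers by default (a Benjamini–Hochberg
option exists) — the selection step treats the p-values as a screen, not
as inference.

## Wavelength selection

**MC-UVE**: 500 subsample fits (80% of training rows) at the full-model
LOO-selected A; stability sⱼ = mean(bⱼ)/sd(bⱼ); cutoff = 99th percentile of
|s| over appended artificial noise columns (the classical UVE
noise-augmentation rule).  A large-but-unstable coefficient is discarded,
which is the method's point.  Stability is exactly scale-equivariant only
at full rank (where the fits collapse to least squares); at A < rank the
equivariance is approximate, as for PLS coefficients generally.

**β-selection** (the pipeline default): keep wavenumbers that are
statistically significant (jack-knife p < 0.05) *and* sit at peaks or
valleys of the β curve (strict local extrema over the wavenumber axis,
leftmost index on plateaus).  A top-|β|-quantile rule is the alternative.
If no coefficient passes the significance screen — the expected outcome for
a no-signal response such as cohesiveness — the pipeline falls back to the
β-curve extrema alone, logs the fallback, and records it in the report, so
the model comparison can still be made.  For texture responses the berry
equatorial diameter is appended *after* selection as the final predictor
column; it never participates in, and cannot be eliminated by, wavelength
selection.

## The network

Input:hidden:output = (n+1) : ⌈(n+1)/2⌉ : 1 for n predictors; the "+1" is
realized as an appended constant-1 input column so the literal width rule
holds (`plus_one: none` drops it — the two interpretations of the extra
unit are both available, constant column being the default).  The hidden
width rounds up because n+1 is usually odd.  ReLU on the two hidden
layers, linear output, He-normal initialization (SD = √(2/fan_in)), L1
penalty (λ = 10⁻⁴ by default) on the first two layers' weights, Adam
(lr 10⁻³, β₁ 0.9, β₂ 0.999), MSE loss with MAE monitoring, batch 32,
validation split 0.2 of the training partition, 1000 epochs with the
best-validation-loss weights restored afterwards (the split exists to
checkpoint, not to early-stop).  All stochastic stages — initialization,
the validation split, batch shuffling — draw from one seeded generator, so
a fixed seed reproduces training exactly on a single thread.  The trainer
is a compact dense-network implementation in NumPy; at this problem size
(≤ a few hundred predictors, ≤ 250 samples) each full training run takes
seconds.

The outer Kennard–Stone 80/20 split and the inner 0.2 validation split are
deliberately distinct: the test set never touches training, and the inner
split only selects the checkpoint.  "Training (CV)" rows report LOO-CV
predictions for PLS and inner-validation predictions for the ANN, labeled
as such in the report.

## Evaluation

bias = mean(ŷ−y); RMSE = √mean((ŷ−y)²); SEP = sample SD of the residuals;
R² = 1 − SSE/SST (the coefficient of determination; the squared Pearson
correlation is reported alongside as `r2_pearson`); RPD = SD(y)/SEP, the
conventional direction in which RPD > 2 marks a quantitatively useful
calibration — the occasionally-seen inverted phrasing ("SEP over SD")
contradicts that usage and is not implemented.  The identity
RMSE² = SEP²(n−1)/n + bias² holds to numerical precision.  Degenerate
cases: perfect prediction reports RPD = ∞; numerically constant nonzero
residuals make RPD undefined and raise.

## Problem sizes and numerical choices

Default pipeline scale is the full study (270 berries × 1001 grid points);
replicate suites in the tests and the acceptance script use 10 seeds at
200 network epochs, and unit tests use a 24-berry, 101-point profile.
PCA is SVD-based with the largest-|loading| sign convention, so all
decompositions are deterministic.  Dot products on coefficient-path slices
are made contiguous so that cross-validated predictions match naive refit
loops bitwise.  Savitzky–Golay derivative signs follow the ascending
physical coordinate; on the descending stored grid the magnitude is
asserted.  χ² degrees of freedom are clamped to [1, 250].

## Known limitations

- The generator's linear concentration links make TSS nearly ideal for
  PLS; real matrices show band shifts and temperature effects that degrade
  linear models sooner.
- Robust-limit screening at α = 0.01 on clean data still removes ≈1–2% of
  honest samples; this is inherent to any fixed-level screen.
- The β-curve "peaks and valleys" rule is a qualitative criterion made
  precise as strict local extrema; other formalizations (prominence
  thresholds, plateau handling) would select slightly different sets.
- Single-response PLS only; multi-response SIMPLS, kernel/O-PLS and
  interval-PLS variants are out of scope, as are EMSC/detrending/OSC
  pre-treatments, CARS/GA selection, and deeper or regularization-searched
  networks.
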