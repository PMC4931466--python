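# Methods

## Kinetic model

The forward signal model is a single-compartment pCASL model in which the
labelled bolus decays at the longitudinal relaxation rate of arterial blood
from the moment of labelling until imaging, with no exchange into the
tissue compartment and no venous outflow.  A label element created at time
u ∈ [0, τ] reaches the voxel after the transit time ATT and is imaged at
t = τ + w; integrating the surviving label over the labelling window gives
the closed form

ΔM(w) = 2 α M0 (f_SI/λ) (1/R) · [exp(−max(ATT, w)·R) − exp(−(w+τ)·R)],

zero for w + τ ≤ ATT.  The implementation was checked against a direct
numerical quadrature of that delivery integral before the analytic form was
frozen into the tests.

Assumptions worth making explicit: plug flow (no bolus dispersion), a
single relaxation rate (blood) for the label's entire history, ideal
labelling efficiency captured by a scalar α, and no background-suppression
effects.  These match the constant set used throughout the package (only a
blood R is specified) and are standard for weighted-delay processing.

## The weighted delay and its inversion

WD = Σ w(i)·ΔM(i) / Σ ΔM(i) is a ratio statistic: flow and M0 cancel, so
WD depends on acquisition constants and ATT only.  A direct consequence of
the blood-decay-only model is that for ATT ≤ min(w(i)) every delay sees the
fully arrived bolus and ΔM(i) ∝ exp(−w(i)·R) − exp(−(w(i)+τ)·R) is
independent of ATT: the WD(ATT) curve is exactly flat below the shortest
delay (at 1880.012 ms for the default constants) and strictly increasing
above it.  Transit times below the shortest post-labelling delay are
therefore not identifiable with this protocol/model combination — a
physical property of the estimator, not a numerical artifact.

The lookup table is built on a uniform ATT grid over the identifiable
range, default [1400, 3000] ms at 1 ms (sub-millisecond transit-time
precision is physically meaningless).  `build_wd_lookup` refuses a range on
which the curve is not strictly increasing and names the largest monotone
sub-range.  Inversion is monotone piecewise-linear interpolation; WD values
outside the tabulated range clamp to the range ends, and non-finite WD
(voxels whose summed difference signal does not exceed the configurable
noise floor ε, default 0) maps to NaN.  Noiseless round-trips recover ATT
to well under the grid step.

## CBF quantification

Per-delay CBF uses the arrival-complete inversion of the same model
(leading decay term exp(−w·R), no ATT term), scaled by 6000 to
ml/100g/min; the final CBF is the mean over delays with defined values.
When the true transit time exceeds a delay, this formula underestimates
flow by the closed-form factor
[exp(−max(ATT,w)R) − exp(−(w+τ)R)] / [exp(−wR) − exp(−(w+τ)R)],
exposed as `cbf_bias_factor` and asserted in the tests; passing the
transit-time map to `cbf_at_delay(..., att=...)` switches to the
transit-corrected variant for sensitivity analyses.  λ is treated as the
dimensionless ratio 0.9; R is stored in s⁻¹ and converted to per-ms once;
all times are ms internally.

## Synthetic phantom

The generator emulates a two-cohort perfusion study, not anatomy: an
ellipsoidal "brain" (uniform M0 = 1000 a.u., zero background) on a
32×32×24 grid of 3.44×3.44×5 mm voxels — a desk-scale stand-in for a
normalized whole-brain grid; all subjects share the common space, so
registration is out of scope and motion correction is a documented no-op
hook.  Baselines are grey-matter-like: CBF 60 ml/100g/min, ATT 1600 ms
(chosen inside the protocol's identifiable transit-time window).
Between-subject variability is multiplicative on CBF (SD 5%) and additive
on ATT (SD 50 ms).  Spherical ROIs carry patient-only effects; defaults are
+300 ms ATT in one sphere and +15 ml/100g/min CBF in another (the effect
magnitudes are configurable; no empirical values exist for them).  The
patients' ROI transit-time effect is modulated by the age-at-onset
covariate as att_effect + slope·(onset − 12), and
`covariate_slope_for_r` calibrates the slope to a target population
correlation using the Monte-Carlo SD of the truncated onset distribution.

Clinical covariates follow the reference cohort: 21 patients (ages
N(17.1, 4.7²) truncated to [9, 25], onset N(12.0, 3.8²) truncated to
[1, age]) vs 24 controls (N(19.7, 3.5²) on [9, 24]), with the reference
gender composition (10/11 and 9/15) assigned exactly.

Frames are control = M0 + noise and tag = M0 − ΔM + noise with independent
white Gaussian noise of SD noise_sigma·M0 per voxel (default 0.005), 12
pairs per delay.  Everything derives from one master seed via per-subject,
per-delay seed sequences, so runs are byte-identical.  What the phantom
does **not** emulate — anatomy, partial volume, motion, physiological and
temporally correlated noise, background-suppression residuals, bolus
dispersion — bounds what passing tests show: they validate the estimator
chain and its statistical calibration, not robustness to scanner artifacts.

## Group statistics

Pooled-variance two-sample t per in-mask voxel (no covariates), two-tailed
p from the t distribution with n₁+n₂−2 df; voxels undefined in any subject
are dropped from the test mask, and zero-pooled-variance voxels get t=0,
p=1 and a log note.  Benjamini–Hochberg adjustment is applied per parameter
map (ATT, mean CBF, each per-delay CBF separately); significance means
adjusted p < q (default 0.05).  Clusters are connected components of the
significance mask (default 18-connectivity, configurable 6/26) with a
minimum extent (default 100 voxels) applied after thresholding; the peak is
the voxel of maximal |t| with ties broken by smallest linear index, reported
in mm through the affine.  Smoothing (6 mm FWHM, σ = FWHM/(2√(2 ln 2)) per
axis in voxel units, mask-renormalised so constants and in-mask means are
preserved and NaNs neither leak nor spread) is applied to the quantified
parameter maps before group testing; smoothing maps rather than the raw
difference images keeps the nonlinear WD→ATT step on unmixed voxel data.

## Numerical and design choices

- Undefined values are NaN everywhere (never zero), so they cannot bias
  group statistics; means and ROI extractions skip them explicitly.
- Subtraction order is control − tag; a negative in-mask median triggers a
  tag/control-ordering warning rather than silent sign flipping.
- The brain mask is M0 > 0.2 × 99th percentile of M0.
- Noise is generated in float32 for speed; signals and all quantification
  run in float64.

## Validation studies and their sizes

The study drivers in `mdasl.experiments` (shared by the test suite and
`scripts/acceptance.py`) use: a 16³ grid with 10+10 subjects and 200
replicates for the null FDR family-positive rate; the full default phantom
with 21 vs 24 subjects and 50 replicates for planted-effect detection; 500
truth-level replicates on a 16×16×12 grid for correlation recovery (the
statistic does not depend on grid size); 500 noiseless signal pairs for
transit-time round-trips.

## Known limitations

- Transit times below the shortest delay (1400 ms here) are unidentifiable
  under the blood-decay-only model; the inversion clamps there.  At the
  default noise level the per-voxel ATT noise is large relative to the
  WD(ATT) slope, so clamping introduces a baseline-dependent bias that
  attenuates recovered group differences (the acceptance report measures
  this directly); cluster detection is unaffected at the default effect
  size.
- The arrival-complete CBF formula is biased where ATT > w; the bias is
  known in closed form and a corrected variant exists, but the default
  mirrors standard practice for this acquisition.
- FDR control relies on BH under positive dependence (smoothed maps);
  cluster-level inference is extent-filtering only, not a calibrated
  cluster p-value.
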