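# mdasl — multi-delay pCASL perfusion quantification and group analysis

`mdasl` implements the analysis chain of a multi-delay, multi-parametric
pseudo-continuous arterial spin labelling (pCASL) perfusion MRI study: it
turns per-delay tag/control image series into voxel-wise maps of arterial
transit time (ATT) and cerebral blood flow (CBF), and compares two cohorts
(e.g. patients vs healthy controls) voxel by voxel with FDR and
cluster-extent thresholding.  Because single-delay ASL confounds perfusion
with transit time, multi-delay protocols acquire the perfusion-weighted
difference signal ΔM(i) at several post-labelling delays w(i) and estimate
both parameters.  The package is aimed at perfusion-MRI methodologists who
want a tested, scriptable reference for the weighted-delay approach, and it
ships a synthetic two-cohort phantom generator so every stage can be
validated against known ground truth.

## The model

For labelling duration τ, blood longitudinal relaxation rate R, labelling
efficiency α, partition coefficient λ and transit time ATT, the
single-compartment pCASL difference signal at delay w is

    ΔM(w) = 2 α M0 (f/λ) (1/R) · [exp(−max(ATT, w)·R) − exp(−(w+τ)·R)]

(zero before the bolus arrives, w + τ ≤ ATT), with f the perfusion.  The
**weighted delay**

    WD = Σᵢ w(i)·ΔM(i) / Σᵢ ΔM(i)

is independent of f and M0 and increases monotonically with ATT wherever
the signal shape across delays carries transit-time information — i.e. for
ATT above the shortest delay; `mdasl` tabulates the theoretical WD(ATT)
curve and inverts it by monotone interpolation (clamping below the shortest
delay, where the curve is flat under this model).  Per-delay CBF uses the
arrival-complete quantification

    CBF(i) = 6000 · λ · ΔM(i) · R / (2 α M0 · [exp(−w(i)·R) − exp(−(w(i)+τ)·R)])

in ml/100g/min, and the final CBF is the mean across delays.  Group
comparisons use a pooled-variance two-sample t-test per voxel,
Benjamini–Hochberg FDR at q < 0.05 per parameter map, and an extent
threshold (default 100 voxels, 18-connectivity).  Defaults follow a 3 T
protocol: w(i) = 1400/1800/2200/2600 ms, τ = 1500 ms, λ = 0.9, R = 0.61 s⁻¹,
α = 0.8, 12 tag/control pairs per delay, 6 mm FWHM smoothing.

## Worked example

Quantify one synthetic patient at the default study conditions:

```python
from mdasl import (PhantomSpec, make_cohort, build_truth_maps,
                   simulate_subject_series, AcquisitionParams, PerfusionModel)

params = AcquisitionParams()
spec = PhantomSpec(seed=7)                       # 32x32x24, 21+24 cohort
rec = [r for r in make_cohort(spec) if r.group == "patient"][0]
truth = build_truth_maps(spec, rec)              # ground-truth CBF/ATT maps
subject = simulate_subject_series(truth, spec, params, rec)
result = PerfusionModel(subject).fit(smooth_fwhm_mm=6.0)
print(result.summary())
```

```
Multi-delay ASL quantification — subject pat001
  delays (ms): 1400, 1800, 2200, 2600
  in-mask voxels: 8368 of 24576
  voxels with defined ATT: 8368
  ATT (ms):  median 1633,  IQR [1573, 1705]
  CBF (ml/100g/min):  median 55.5,  IQR [52.6, 58.4]
```

The phantom's baseline is ATT 1600 ms and CBF 60 ml/100g/min; the median
ATT lands on the baseline (plus this subject's random offset), and the
median CBF sits slightly below 60 because the arrival-complete formula
underestimates flow at delays shorter than the local transit time — a bias
the package exposes in closed form (`cbf_bias_factor`).

A full study analogue — simulate both cohorts, quantify, smooth, compare —
runs from the command line:

```sh
mdasl run-all --config study.yaml --seed 5 --out report/
```

and writes `cohort.tsv`, per-parameter cluster tables, ROI–covariate
correlations and a demographics table.  On a small high-contrast example
(16×16×12 grid, 6 vs 6 subjects, +600 ms planted ATT effect) the ATT
cluster table reads:

```
 cluster_id  n_voxels  peak_x_mm  peak_y_mm  peak_z_mm  peak_t    min_q     sign
          1        99      10.32      24.08         35 20.8903 0.000002 increase
```

a single surviving cluster whose peak lies inside the planted region: the
patients' transit time is significantly prolonged there.

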