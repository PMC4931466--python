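"""Validation studies run by the test suite and the acceptance script.

Each driver sets up a phantom study through the public package surface,
runs it end to end, and returns plain numbers.  Problem sizes are the
package's validation defaults: the null-error study uses a reduced 16^3
grid with 10+10 subjects, the detection study the full default phantom with
the reference cohort sizes, and the correlation study a truth-level
16x16x12 grid (the statistic does not depend on grid size).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .params import AcquisitionParams, RunConfig
from . import kinetics
from .phantom import (PhantomSpec, ROISphere, make_cohort, cohort_dataframe,
                      build_truth_maps, simulate_subject_series, roi_mask,
                      covariate_slope_for_r)
from .quantify import PerfusionModel, smooth_gaussian
from .stats import GroupComparison, pearson_correlation, roi_mean
from .workflow import demographics_table

__all__ = [
    "gender_demographics",
    "att_roundtrip_errors",
    "cbf_self_consistency",
    "wd_invariants",
    "null_family_error_rate",
    "planted_effect_detection",
    "correlation_recovery",
]


def _seed_of(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] % (2**31))


def gender_demographics(seed: int = 0):
    """Gender chi-squared of a generated default cohort (chi2, p)."""
    spec = PhantomSpec(seed=_seed_of(seed, 1))
    df = demographics_table(cohort_dataframe(make_cohort(spec)))
    row = df[df.variable == "gender_male_female"].iloc[0]
    return float(row.statistic), float(row.p)


def att_roundtrip_errors(n: int = 500, att_lo: float = 200.0,
                         att_hi: float = 2400.0, seed: int = 0,
                         params: AcquisitionParams | None = None) -> np.ndarray:
    """Absolute transit-time recovery errors (ms) on noiseless signals.

    Random (CBF, ATT) pairs; forward model -> WD -> lookup inversion.
    """
    params = params or AcquisitionParams()
    lookup = kinetics.build_wd_lookup(params)
    rng = np.random.default_rng(_seed_of(seed, 2))
    att = rng.uniform(att_lo, att_hi, size=n)
    cbf = rng.uniform(20.0, 100.0, size=n)
    plds = np.asarray(params.plds)
    dm = np.stack([kinetics.delta_m_model(cbf, att, w, 1000.0, params) for w in plds])
    wd = kinetics.weighted_delay(dm, plds)
    rec = kinetics.wd_to_att(wd, lookup)
    return np.abs(rec - att)


def cbf_self_consistency(params: AcquisitionParams | None = None, seed: int = 0):
    """(max relative CBF error at ATT=0, max |measured bias - closed form|).

    Noiseless forward signals quantified by the arrival-complete formula:
    at ATT=0 every delay must return the true CBF; at ATT>0 the per-delay
    under/over-estimation factor must match :func:`kinetics.cbf_bias_factor`.
    """
    params = params or AcquisitionParams()
    rng = np.random.default_rng(_seed_of(seed, 3))
    plds = np.asarray(params.plds)
    cbf_true = rng.uniform(20.0, 100.0, size=50)
    rel_err = 0.0
    for w in plds:
        dm = kinetics.delta_m_model(cbf_true, 0.0, w, 1000.0, params)
        est = kinetics.cbf_at_delay(dm, 1000.0, w, params)
        rel_err = max(rel_err, float(np.max(np.abs(est / cbf_true - 1.0))))
    att = rng.uniform(0.0, 2800.0, size=200)
    bias_dev = 0.0
    for w in plds:
        dm = kinetics.delta_m_model(60.0, att, w, 1000.0, params)
        est = kinetics.cbf_at_delay(dm, 1000.0, w, params)
        expected = kinetics.cbf_bias_factor(att, w, params)
        bias_dev = max(bias_dev, float(np.max(np.abs(est / 60.0 - expected))))
    return rel_err, bias_dev


def wd_invariants(n_vectors: int = 10_000, seed: int = 0,
                  params: AcquisitionParams | None = None):
    """WD statistic invariants.

    Returns (fraction of 1-ms steps on [0, 2600] where WD(ATT) strictly
    increases, number of bound violations over random nonnegative signal
    vectors).  The theoretical curve is flat below the shortest delay, so
    the increasing fraction reflects exactly the estimable sub-range.
    """
    params = params or AcquisitionParams()
    plds = np.asarray(params.plds)
    att = np.arange(0.0, 2600.0 + 0.5, 1.0)
    dm = np.stack([kinetics.delta_m_model(60.0, att, w, 1000.0, params) for w in plds])
    wd_curve = kinetics.weighted_delay(dm, plds)
    frac_increasing = float(np.mean(np.diff(wd_curve) > 0))
    rng = np.random.default_rng(_seed_of(seed, 4))
    vecs = rng.uniform(0.0, 1.0, size=(len(plds), n_vectors))
    wd = kinetics.weighted_delay(vecs, plds)
    ok = np.isfinite(wd)
    violations = int(np.sum((wd[ok] < plds.min() - 1e-9) | (wd[ok] > plds.max() + 1e-9)))
    return frac_increasing, violations


def _null_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(shape=(16, 16, 16), rois=(), n_patients=10,
                       n_controls=10, seed=seed)


def null_family_error_rate(n_sims: int = 200, seed: int = 0,
                           config: RunConfig | None = None):
    """Fraction of no-effect simulations with >= 1 FDR-significant ATT voxel.

    Each simulation draws a fresh 10+10 cohort on a 16^3 phantom with no
    planted effects and runs the full pipeline (simulate, quantify, smooth,
    pooled t, per-map BH at q=0.05).  Returns (rate, n_sims).
    """
    config = config or RunConfig()
    ana = config.analysis
    lookup = kinetics.build_wd_lookup(config.acquisition, ana["att_min"],
                                      ana["att_max"], ana["att_step"])
    hits = 0
    for s in range(n_sims):
        spec = _null_spec(_seed_of(seed, 100 + s))
        fit, _ = _run_att_comparison(spec, config, lookup, extent=1)
        hits += int(fit.sig_mask.any())
    return hits / n_sims, n_sims


def _run_att_comparison(spec, config, lookup, extent):
    """Simulate one cohort, quantify, smooth the transit-time maps and run
    the patient-vs-control comparison.  Returns (fitted comparison, per-group
    unsmoothed quantified maps)."""
    ana = config.analysis
    records = make_cohort(spec)
    smoothed = {"patient": [], "control": []}
    raw = {"patient": [], "control": []}
    masks = []
    affine = spec.affine()
    for rec in records:
        truth = build_truth_maps(spec, rec)
        subject = simulate_subject_series(truth, spec, config.acquisition, rec)
        res = PerfusionModel(subject, lookup, ana["mask_frac"],
                             ana["epsilon"]).fit()
        raw[rec.group].append(res)
        smoothed[rec.group].append(
            smooth_gaussian(res.att, ana["fwhm_mm"], affine, res.mask))
        masks.append(res.mask)
    mask = np.logical_and.reduce(masks)
    comp = GroupComparison(np.stack(smoothed["patient"]),
                           np.stack(smoothed["control"]), mask, affine, "att")
    return comp.fit(ana["q_level"], extent, ana["connectivity"]), raw


def planted_effect_detection(n_seeds: int = 50, seed: int = 0,
                             config: RunConfig | None = None):
    """Detection study at the reference cohort sizes on the default phantom.

    For each replicate: simulate 21 patients (+300 ms transit-time effect in
    the spherical ROI) vs 24 controls, quantify, smooth, compare ATT maps
    with FDR q<0.05 and a 100-voxel extent.  A replicate counts as a
    detection when a surviving cluster's peak lies inside the planted ROI.

    Returns (detection rate, mean recovered ROI group difference in ms,
    n_seeds).
    """
    config = config or RunConfig()
    ana = config.analysis
    lookup = kinetics.build_wd_lookup(config.acquisition, ana["att_min"],
                                      ana["att_max"], ana["att_step"])
    hits = 0
    diffs = []
    for s in range(n_seeds):
        spec = PhantomSpec(seed=_seed_of(seed, 200 + s))
        roi = roi_mask(spec, "stg_att")
        fit, raw = _run_att_comparison(spec, config, lookup, ana["extent"])
        inv_aff = np.linalg.inv(fit.stat_map.affine)
        for _, cl in fit.clusters.iterrows():
            vox = inv_aff @ np.array([cl.peak_x_mm, cl.peak_y_mm, cl.peak_z_mm, 1.0])
            idx = tuple(int(round(v)) for v in vox[:3])
            if roi[idx]:
                hits += 1
                break
        pat_roi = np.mean([roi_mean(r.att, roi) for r in raw["patient"]])
        con_roi = np.mean([roi_mean(r.att, roi) for r in raw["control"]])
        diffs.append(pat_roi - con_roi)
    return hits / n_seeds, float(np.mean(diffs)), n_seeds


def correlation_recovery(n_reps: int = 500, seed: int = 0,
                         target_r: float = -0.5):
    """Mean estimated onset-age correlation across truth-level replicates.

    The covariate slope is calibrated for population correlation
    ``target_r`` between onset age and the ROI transit time at the patient
    cohort size; each replicate samples a cohort, builds the ground-truth
    maps, extracts the ROI mean and computes Pearson r.

    Returns (mean r, n_reps).
    """
    base = PhantomSpec(
        shape=(16, 16, 12),
        rois=(ROISphere("stg_att", (5, 8, 6), 10.0, att_effect=300.0),),
    )
    slope = covariate_slope_for_r(target_r, base, seed=_seed_of(seed, 5))
    rs = []
    for rep in range(n_reps):
        spec = replace(base, covariate_slope=slope, seed=_seed_of(seed, 300 + rep))
        roi = roi_mask(spec, "stg_att")
        patients = [r for r in make_cohort(spec) if r.group == "patient"]
        vals = [roi_mean(build_truth_maps(spec, rec)[1], roi) for rec in patients]
        onset = [rec.age_at_onset for rec in patients]
        r, _ = pearson_correlation(vals, onset)
        rs.append(r)
    return float(np.mean(rs)), n_reps
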