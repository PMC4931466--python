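"""Synthetic two-cohort multi-delay ASL phantom.

Emulates a patient/control perfusion study: an ellipsoidal "brain" of
uniform equilibrium magnetization, subject-level CBF/ATT variability,
spherical regions of interest in which the patient group carries planted
CBF and/or transit-time effects, a clinical covariate (age at onset) that
modulates the transit-time effect, and per-delay tag/control image series
with white Gaussian noise.

Cohort demographics follow the reference absence-seizure study population:
21 patients (10 M / 11 F), ages ~ N(17.1, 4.7^2) truncated to [9, 25],
onset age ~ N(12.0, 3.8^2) truncated to [1, age]; 24 controls (9 M / 15 F),
ages ~ N(19.7, 3.5^2) truncated to [9, 24].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .params import AcquisitionParams
from .kinetics import delta_m_model

__all__ = [
    "ROISphere",
    "PhantomSpec",
    "SubjectRecord",
    "make_cohort",
    "cohort_dataframe",
    "build_truth_maps",
    "roi_mask",
    "brain_mask",
    "simulate_subject_series",
    "covariate_slope_for_r",
    "COHORT_GENDER_COUNTS",
]

#: gender composition (male, female) of the reference cohorts
COHORT_GENDER_COUNTS = {"patient": (10, 11), "control": (9, 15)}

_AGE_MODEL = {
    "patient": dict(mean=17.1, sd=4.7, lo=9.0, hi=25.0),
    "control": dict(mean=19.7, sd=3.5, lo=9.0, hi=24.0),
}
_ONSET_MODEL = dict(mean=12.0, sd=3.8, lo=1.0)


@dataclass(frozen=True)
class ROISphere:
    """Spherical ROI in common (voxel-grid) space with planted group effects."""

    name: str
    center_vox: tuple  # (i, j, k) voxel indices
    radius_mm: float
    cbf_effect: float = 0.0  # ml/100g/min added in patients
    att_effect: float = 0.0  # ms added in patients


@dataclass(frozen=True)
class PhantomSpec:
    """Study-condition description of the synthetic phantom."""

    shape: tuple = (32, 32, 24)
    voxel_size: tuple = (3.44, 3.44, 5.0)  # mm
    baseline_cbf: float = 60.0  # ml/100g/min, grey-matter-like
    baseline_att: float = 1600.0  # ms, within the protocol's estimable range
    m0_value: float = 1000.0  # a.u. inside the brain
    rois: tuple = (
        ROISphere("stg_att", (9, 16, 12), 14.0, att_effect=300.0),
        ROISphere("mtg_cbf", (23, 16, 12), 14.0, cbf_effect=15.0),
    )
    noise_sigma: float = 0.005  # frame noise SD as a fraction of local M0
    n_patients: int = 21
    n_controls: int = 24
    between_subject_cbf_sd: float = 0.05  # multiplicative, fraction of baseline
    between_subject_att_sd: float = 50.0  # additive, ms
    covariate_slope: float = 0.0  # ms of ATT effect per year of onset age
    onset_ref: float = 12.0  # years; slope acts on (onset - onset_ref)
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        for roi in self.rois:
            if not all(0 <= c < s for c, s in zip(roi.center_vox, self.shape)):
                raise ValueError(f"ROI {roi.name} centre outside the grid")

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    gender: str  # "M" | "F"
    age: float  # years
    age_at_onset: float | None  # years, patients only
    illness_duration: float | None  # years, patients only
    seed_offset: int

    def __post_init__(self):
        if self.group == "patient":
            if self.age_at_onset is None or self.illness_duration is None:
                raise ValueError("patients need onset age and illness duration")
            if abs(self.illness_duration - (self.age - self.age_at_onset)) > 1e-6:
                raise ValueError("illness_duration must equal age - age_at_onset")
        elif self.group == "control":
            if self.age_at_onset is not None or self.illness_duration is not None:
                raise ValueError("controls carry no onset variables")
        else:
            raise ValueError(f"unknown group {self.group!r}")


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_cohort(spec: PhantomSpec) -> list[SubjectRecord]:
    """Sample the two cohorts' clinical records, deterministically in seed.

    Gender labels are assigned to match the reference cohort composition
    (scaled proportionally for non-default group sizes).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0]))
    records: list[SubjectRecord] = []
    offset = 0
    for group, n in (("patient", spec.n_patients), ("control", spec.n_controls)):
        m_ref, f_ref = COHORT_GENDER_COUNTS[group]
        n_male = int(round(n * m_ref / (m_ref + f_ref)))
        am = _AGE_MODEL[group]
        ages = _trunc_normal(rng, am["mean"], am["sd"], am["lo"], am["hi"], size=n)
        for i in range(n):
            age = float(ages[i])
            onset = duration = None
            if group == "patient":
                onset = float(
                    _trunc_normal(rng, _ONSET_MODEL["mean"], _ONSET_MODEL["sd"],
                                  _ONSET_MODEL["lo"], age)
                )
                duration = age - onset
            records.append(
                SubjectRecord(
                    subject_id=f"{group[:3]}{i + 1:03d}",
                    group=group,
                    gender="M" if i < n_male else "F",
                    age=age,
                    age_at_onset=onset,
                    illness_duration=duration,
                    seed_offset=offset,
                )
            )
            offset += 1
    return records


def cohort_dataframe(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                subject_id=r.subject_id,
                group=r.group,
                gender=r.gender,
                age=r.age,
                age_at_onset=r.age_at_onset,
                illness_duration=r.illness_duration,
            )
            for r in records
        ]
    )


def brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoidal brain support, semi-axes ~85% of the half-grid."""
    nx, ny, nz = spec.shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.875 * nx / 2, 0.875 * ny / 2, 0.85 * nz / 2
    i, j, k = np.ogrid[:nx, :ny, :nz]
    return ((i - cx) / ax) ** 2 + ((j - cy) / ay) ** 2 + ((k - cz) / az) ** 2 <= 1.0


def roi_mask(spec: PhantomSpec, roi: ROISphere | str) -> np.ndarray:
    """Boolean volume of one spherical ROI (named or given directly)."""
    if isinstance(roi, str):
        match = [r for r in spec.rois if r.name == roi]
        if not match:
            raise KeyError(f"no ROI named {roi!r}")
        roi = match[0]
    i, j, k = np.ogrid[: spec.shape[0], : spec.shape[1], : spec.shape[2]]
    dx = (i - roi.center_vox[0]) * spec.voxel_size[0]
    dy = (j - roi.center_vox[1]) * spec.voxel_size[1]
    dz = (k - roi.center_vox[2]) * spec.voxel_size[2]
    return dx**2 + dy**2 + dz**2 <= roi.radius_mm**2


def _subject_rng(spec: PhantomSpec, record: SubjectRecord, stream: int):
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(record.seed_offset), stream])
    )


def build_truth_maps(spec: PhantomSpec, record: SubjectRecord):
    """Ground-truth CBF and ATT volumes for one subject.

    Baseline plus a subject-level offset everywhere in the brain; patients
    additionally receive each ROI's planted effect, with the transit-time
    effect modulated by the onset-age covariate:
    ``att_effect + covariate_slope * (age_at_onset - onset_ref)``.

    Returns
    -------
    (cbf, att) : pair of float volumes (zero outside the brain).
    """
    mask = brain_mask(spec)
    rng = _subject_rng(spec, record, stream=1)
    cbf_scale = 1.0 + spec.between_subject_cbf_sd * rng.standard_normal()
    att_shift = spec.between_subject_att_sd * rng.standard_normal()
    cbf = np.where(mask, spec.baseline_cbf * max(cbf_scale, 0.1), 0.0)
    att = np.where(mask, spec.baseline_att + att_shift, 0.0)
    if record.group == "patient":
        for roi in spec.rois:
            rmask = roi_mask(spec, roi) & mask
            att_eff = roi.att_effect
            if roi.att_effect != 0.0 and spec.covariate_slope != 0.0:
                att_eff = att_eff + spec.covariate_slope * (
                    record.age_at_onset - spec.onset_ref
                )
            cbf[rmask] += roi.cbf_effect
            att[rmask] += att_eff
    np.clip(att, 0.0, None, out=att)
    return cbf, att


def simulate_subject_series(truth, spec: PhantomSpec, params: AcquisitionParams,
                            record: SubjectRecord):
    """Simulate one subject's per-delay tag/control series plus M0 volume.

    Per delay, ``params.n_pairs`` tag and control frames:
    control = M0 + noise, tag = M0 - dM(truth, w) + noise, with independent
    white Gaussian noise of SD ``noise_sigma * M0`` per voxel (so background
    voxels with M0 = 0 are exactly zero in every frame).

    Returns a :class:`mdasl.quantify.SubjectASL`.
    """
    from .quantify import SubjectASL  # deferred: quantify imports params only

    cbf, att = truth
    if cbf.shape != tuple(spec.shape) or att.shape != tuple(spec.shape):
        raise ValueError("truth maps do not match spec.shape")
    m0 = np.where(brain_mask(spec), spec.m0_value, 0.0)
    sd = spec.noise_sigma * m0
    series = {}
    for ip, w in enumerate(params.plds):
        dm = delta_m_model(cbf, att, w, m0, params)
        rng = _subject_rng(spec, record, stream=10 + ip)
        shape = (params.n_pairs,) + tuple(spec.shape)
        controls = m0 + sd * rng.standard_normal(shape, dtype=np.float32)
        tags = (m0 - dm) + sd * rng.standard_normal(shape, dtype=np.float32)
        series[w] = (tags, controls)
    return SubjectASL(
        series=series,
        m0=m0,
        affine=spec.affine(),
        params=params,
        subject_id=record.subject_id,
    )


def covariate_slope_for_r(target_r: float, spec: PhantomSpec,
                          n_mc: int = 50_000, seed: int = 12345) -> float:
    """Covariate slope (ms/year) giving population correlation ``target_r``
    between onset age and the ROI transit time in patients.

    The ROI transit time is baseline + subject ATT offset (SD
    ``between_subject_att_sd``) + slope * (onset - onset_ref), so
    ``|slope| * sd_onset = sd_att * |r| / sqrt(1 - r^2)``.  The onset SD
    under the truncated sampling model is estimated once by Monte Carlo.
    """
    if not (-1.0 < target_r < 1.0) or target_r == 0.0:
        raise ValueError("target_r must be in (-1, 1) and nonzero")
    rng = np.random.default_rng(seed)
    am = _AGE_MODEL["patient"]
    ages = _trunc_normal(rng, am["mean"], am["sd"], am["lo"], am["hi"], size=n_mc)
    lo = _ONSET_MODEL["lo"]
    a = (lo - _ONSET_MODEL["mean"]) / _ONSET_MODEL["sd"]
    b = (ages - _ONSET_MODEL["mean"]) / _ONSET_MODEL["sd"]
    u = rng.uniform(size=n_mc)
    cdf_a = stats.norm.cdf(a)
    onset = stats.norm.ppf(cdf_a + u * (stats.norm.cdf(b) - cdf_a))
    onset = _ONSET_MODEL["mean"] + _ONSET_MODEL["sd"] * onset
    sd_onset = onset.std()
    mag = spec.between_subject_att_sd * abs(target_r) / np.sqrt(1.0 - target_r**2)
    return float(np.sign(target_r) * mag / sd_onset)
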