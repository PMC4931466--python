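"""Forward pCASL kinetic model, weighted-delay statistic and CBF quantification.

The signal model is the single-compartment pCASL model with decay of the
label at the blood longitudinal rate only (no exchange into tissue, no
outflow).  For a voxel with perfusion f (ml/100g/min), transit time ``att``
(ms) and post-labelling delay ``w`` (ms) the perfusion-weighted difference
signal is

    dM(w) = 2 a M0 (f_SI / lam) (1/R) [exp(-max(att, w) R) - exp(-(w+tau) R)]

for ``att <= w + tau`` and zero otherwise, with R in per-ms and f_SI the
perfusion converted to per-ms units.  The weighted delay

    WD = sum_i w(i) dM(i) / sum_i dM(i)

is a flow-independent, monotone surrogate for the transit time wherever the
shape of dM across delays changes with ``att`` — that is, for
``att >= min(plds)``.  Below the shortest delay the bolus has fully arrived
at every delay and the signal shape (hence WD) carries no transit-time
information; the lookup table therefore declares an invertible range that
starts at the shortest delay and the inversion clamps below it.

Per-delay CBF uses the arrival-complete form of the same model
(no transit-time term), which is exact whenever ``att <= w``:

    CBF(i) = 6000 lam dM(i) R_s /
             (2 a M0 [exp(-w(i) R) - exp(-(w(i)+tau) R)])

with the 6000 factor converting ml g^-1 s^-1 to ml/100g/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AcquisitionParams

__all__ = [
    "delta_m_model",
    "weighted_delay",
    "WDLookup",
    "build_wd_lookup",
    "wd_to_att",
    "cbf_at_delay",
    "cbf_bias_factor",
    "mean_cbf",
]

#: ml/100g/min -> ml g^-1 ms^-1
_CBF_TO_PER_MS = 1.0 / 6.0e6


def delta_m_model(cbf, att, w, m0, params: AcquisitionParams):
    """Perfusion-weighted difference signal of the forward kinetic model.

    Parameters
    ----------
    cbf : array_like
        Perfusion in ml/100g/min, >= 0.
    att : array_like
        Arterial transit time in ms, >= 0.
    w : float or array_like
        Post-labelling delay in ms.
    m0 : array_like
        Equilibrium magnetization (arbitrary units), >= 0.
    params : AcquisitionParams

    Returns
    -------
    ndarray or float
        Difference signal in the units of ``m0``; zero wherever the bolus
        has not arrived (``w + tau <= att``).
    """
    cbf = np.asarray(cbf, dtype=float)
    att = np.asarray(att, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if np.any(cbf < 0):
        raise ValueError("cbf must be nonnegative")
    if np.any(m0 < 0):
        raise ValueError("m0 must be nonnegative")
    if np.any(att < 0):
        raise ValueError("att must be nonnegative")
    r = params.r_per_ms
    w = np.asarray(w, dtype=float)
    lead = np.maximum(att, w)
    trail = w + params.tau
    bracket = np.clip(np.exp(-lead * r) - np.exp(-trail * r), 0.0, None)
    out = 2.0 * params.alpha * m0 * (cbf * _CBF_TO_PER_MS / params.lam) / r * bracket
    return out if out.ndim else float(out)


def weighted_delay(delta_m, plds, epsilon: float = 0.0):
    """Signal-weighted mean delay, WD = sum w(i) dM(i) / sum dM(i).

    ``delta_m`` holds one value (or one volume, stacked on the first axis)
    per delay.  Where the summed signal does not exceed ``epsilon`` the
    statistic is undefined and NaN is returned; no division by zero occurs.
    """
    dm = np.asarray(delta_m, dtype=float)
    plds = np.asarray(plds, dtype=float)
    if dm.shape[0] != plds.shape[0]:
        raise ValueError("delta_m and plds lengths differ")
    if plds.shape[0] < 2:
        raise ValueError("need at least 2 delays")
    denom = dm.sum(axis=0)
    num = np.tensordot(plds, dm, axes=(0, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        wd = np.where(denom > epsilon, num / np.where(denom > epsilon, denom, 1.0), np.nan)
    return wd if wd.ndim else float(wd)


@dataclass(frozen=True)
class WDLookup:
    """Monotone tabulation of the theoretical WD(ATT) curve.

    ``wd_values`` is strictly increasing along ``att_grid`` over the declared
    (full) range; flow and M0 cancel in the WD ratio so the table is the same
    for any positive CBF and M0.
    """

    att_grid: np.ndarray
    wd_values: np.ndarray
    params: AcquisitionParams

    @property
    def step(self) -> float:
        return float(self.att_grid[1] - self.att_grid[0])


def build_wd_lookup(
    params: AcquisitionParams,
    att_min: float = 1400.0,
    att_max: float = 3000.0,
    step: float = 1.0,
) -> WDLookup:
    """Tabulate WD(ATT) on a uniform transit-time grid.

    Raises if the curve is not strictly increasing over the requested range,
    naming the largest strictly-monotone sub-range.  For the default protocol
    the curve is flat below the shortest delay, so the default range starts
    there.
    """
    if not (0 <= att_min < att_max):
        raise ValueError("need 0 <= att_min < att_max")
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.arange(att_min, att_max + 0.5 * step, step)
    plds = np.asarray(params.plds)
    dm = np.stack([delta_m_model(60.0, grid, w, 1000.0, params) for w in plds])
    wd = weighted_delay(dm, plds)
    diffs = np.diff(wd)
    if not np.all(diffs > 0):
        inc = diffs > 0
        # longest run of consecutive increases
        best_len, best_start, run, start = 0, 0, 0, 0
        for i, ok in enumerate(inc):
            if ok:
                if run == 0:
                    start = i
                run += 1
                if run > best_len:
                    best_len, best_start = run, start
            else:
                run = 0
        lo = grid[best_start]
        hi = grid[best_start + best_len]
        raise ValueError(
            f"WD(ATT) is not strictly increasing on [{att_min:g}, {att_max:g}] ms; "
            f"largest monotone sub-range is [{lo:g}, {hi:g}] ms"
        )
    return WDLookup(att_grid=grid, wd_values=wd, params=params)


def wd_to_att(wd, lookup: WDLookup):
    """Invert the WD(ATT) table by monotone piecewise-linear interpolation.

    Values below/above the tabulated WD range clamp to the range ends;
    non-finite WD maps to NaN.
    """
    wd = np.asarray(wd, dtype=float)
    att = np.interp(wd, lookup.wd_values, lookup.att_grid)
    att = np.where(np.isfinite(wd), att, np.nan)
    return att if att.ndim else float(att)


def cbf_at_delay(delta_m, m0, w, params: AcquisitionParams, att=None):
    """Per-delay CBF (ml/100g/min) from the arrival-complete quantification.

    Linear in ``delta_m`` and invariant under joint rescaling of ``delta_m``
    and ``m0``.  When ``att`` is given, the leading decay term uses
    ``max(att, w)`` instead of ``w`` (transit-corrected variant for
    sensitivity analysis); the default assumes complete bolus arrival.
    """
    m0 = np.asarray(m0, dtype=float)
    if np.any(m0 <= 0):
        raise ValueError("m0 must be positive")
    if np.any(np.asarray(w) <= 0):
        raise ValueError("w must be positive")
    dm = np.asarray(delta_m, dtype=float)
    r = params.r_per_ms
    lead = w if att is None else np.maximum(att, w)
    bracket = np.exp(-np.asarray(lead, dtype=float) * r) - np.exp(-(w + params.tau) * r)
    out = 6000.0 * params.lam * dm * params.R / (2.0 * params.alpha * m0 * bracket)
    return out if out.ndim else float(out)


def cbf_bias_factor(att, w, params: AcquisitionParams):
    """Closed-form ratio (estimated CBF)/(true CBF) of the arrival-complete
    quantification applied to a signal generated with transit time ``att``.

    Equals 1 for ``att <= w`` and
    ``[exp(-att R) - exp(-(w+tau) R)] / [exp(-w R) - exp(-(w+tau) R)]``
    for ``w < att < w + tau`` (0 beyond, where no signal remains).
    """
    r = params.r_per_ms
    att = np.asarray(att, dtype=float)
    w = np.asarray(w, dtype=float)
    num = np.clip(np.exp(-np.maximum(att, w) * r) - np.exp(-(w + params.tau) * r), 0.0, None)
    den = np.exp(-w * r) - np.exp(-(w + params.tau) * r)
    out = num / den
    return out if out.ndim else float(out)


def mean_cbf(cbf_per_delay):
    """Mean CBF across delays, ignoring undefined (NaN) entries.

    ``cbf_per_delay`` stacks one value or volume per delay on the first
    axis.  All-undefined voxels yield NaN; an empty stack is an error.
    """
    stack = np.asarray(cbf_per_delay, dtype=float)
    if stack.shape[0] == 0:
        raise ValueError("empty per-delay CBF input")
    finite = np.isfinite(stack)
    n = finite.sum(axis=0)
    s = np.where(finite, stack, 0.0).sum(axis=0)
    out = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return out if np.ndim(out) else float(out)
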