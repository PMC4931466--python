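"""Acquisition and run configuration.

Times are handled in milliseconds throughout the package; the blood
longitudinal relaxation rate ``R`` is stored in s^-1 (the unit it is quoted
in) and converted to per-ms exactly once, at parameter load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["AcquisitionParams", "RunConfig", "load_config"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Physical and sequence constants of a multi-delay pCASL protocol.

    Parameters
    ----------
    plds : tuple of float
        Post-labelling delays w(i) in ms, strictly increasing.
    tau : float
        Labelling pulse duration in ms.
    lam : float
        Blood/tissue water partition coefficient (dimensionless, conventionally
        quoted as 0.9 g/ml and used as a pure ratio).
    R : float
        Longitudinal relaxation rate of arterial blood at 3 T, s^-1.
    alpha : float
        Labelling (tagging) efficiency, 0 < alpha <= 1.
    tr : float
        Repetition time in ms (metadata only, not used in quantification).
    n_pairs : int
        Tag/control pairs acquired per delay (metadata; the simulator's
        default pair count).
    """

    plds: tuple = (1400.0, 1800.0, 2200.0, 2600.0)
    tau: float = 1500.0
    lam: float = 0.9
    R: float = 0.61
    alpha: float = 0.8
    tr: float = 3500.0
    n_pairs: int = 12

    def __post_init__(self):
        plds = tuple(float(w) for w in self.plds)
        object.__setattr__(self, "plds", plds)
        if len(plds) < 1 or any(w <= 0 for w in plds):
            raise ValueError("plds must be positive")
        if any(b <= a for a, b in zip(plds, plds[1:])):
            raise ValueError("plds must be strictly increasing")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.lam <= 0:
            raise ValueError("lam must be positive")

    @property
    def r_per_ms(self) -> float:
        """Blood relaxation rate in ms^-1."""
        return self.R / 1000.0


# analysis-stage defaults: FDR level, cluster extent (voxels), component
# connectivity, smoothing FWHM (mm), mask threshold fraction, WD noise floor
_ANALYSIS_DEFAULTS = dict(
    q_level=0.05,
    extent=100,
    connectivity=18,
    fwhm_mm=6.0,
    mask_frac=0.2,
    epsilon=0.0,
    att_min=1400.0,
    att_max=3000.0,
    att_step=1.0,
)


@dataclass
class RunConfig:
    """Full configuration of an end-to-end phantom study."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    phantom: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))
    seed: int = 0
    output_dir: str = "mdasl_run"

    def __post_init__(self):
        merged = dict(_ANALYSIS_DEFAULTS)
        merged.update(self.analysis or {})
        self.analysis = merged

    def to_dict(self) -> dict:
        d = asdict(self)
        d["acquisition"]["plds"] = list(self.acquisition.plds)
        return d


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Read a YAML run configuration; every key has a protocol default.

    Recognised acquisition keys: plds, tau, lambda (or lam), R, alpha, tr,
    n_pairs. ``lambda`` is accepted as the conventional symbol name.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict):
                raw.setdefault(k, {}).update(v)
            else:
                raw[k] = v
    acq = dict(raw.get("acquisition", {}))
    if "lambda" in acq:
        acq["lam"] = acq.pop("lambda")
    cfg = RunConfig(
        acquisition=AcquisitionParams(**acq),
        phantom=dict(raw.get("phantom", {})),
        analysis=dict(raw.get("analysis", {})),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "mdasl_run")),
    )
    return cfg
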