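"""NIfTI and tabular I/O."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .params import AcquisitionParams
from .quantify import SubjectASL, PerfusionResults

__all__ = [
    "read_nifti", "write_nifti", "save_subject", "load_subject",
    "save_maps", "write_table", "read_table",
]


def read_nifti(path):
    """Load a NIfTI-1 volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(volume, affine, path):
    """Write a volume as float32 NIfTI-1; returns the path."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))
    return Path(path)


def save_subject(subject: SubjectASL, outdir) -> Path:
    """Write one subject's series (4D, tags then controls per delay) and M0."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for w, (tags, controls) in subject.series.items():
        frames = np.concatenate([tags, controls], axis=0)  # (2*n_pairs, x, y, z)
        write_nifti(np.moveaxis(frames, 0, -1), subject.affine,
                    outdir / f"asl_pld{int(w)}.nii.gz")
    write_nifti(subject.m0, subject.affine, outdir / "m0.nii.gz")
    meta = dict(
        subject_id=subject.subject_id,
        plds=list(subject.params.plds),
        tau=subject.params.tau, lam=subject.params.lam, R=subject.params.R,
        alpha=subject.params.alpha, tr=subject.params.tr,
        n_pairs={float(w): int(t.shape[0]) for w, (t, _) in subject.series.items()},
    )
    (outdir / "subject.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_subject(subject_dir) -> SubjectASL:
    """Read a subject directory written by :func:`save_subject`."""
    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / "subject.json").read_text())
    params = AcquisitionParams(
        plds=tuple(meta["plds"]), tau=meta["tau"], lam=meta["lam"],
        R=meta["R"], alpha=meta["alpha"], tr=meta.get("tr", 3500.0),
    )
    m0, affine = read_nifti(subject_dir / "m0.nii.gz")
    series = {}
    for w in params.plds:
        path = subject_dir / f"asl_pld{int(w)}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing series for delay {w} ms: {path}")
        data, aff = read_nifti(path)
        if data.shape[:3] != m0.shape or not np.allclose(aff, affine):
            raise ValueError(f"shape/affine mismatch in {path}")
        frames = np.moveaxis(data, -1, 0)
        n = frames.shape[0] // 2
        series[w] = (frames[:n], frames[n:])
    return SubjectASL(series=series, m0=m0, affine=affine, params=params,
                      subject_id=meta.get("subject_id", subject_dir.name))


def save_maps(maps: PerfusionResults, outdir) -> Path:
    """Write quantified maps as NIfTI plus a JSON provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, w in enumerate(maps.params.plds):
        write_nifti(maps.delta_m[i], maps.affine, outdir / f"dm_{int(w)}.nii.gz")
        write_nifti(maps.cbf_per_delay[i], maps.affine, outdir / f"cbf_{int(w)}.nii.gz")
    write_nifti(maps.wd, maps.affine, outdir / "wd.nii.gz")
    write_nifti(maps.att, maps.affine, outdir / "att.nii.gz")
    write_nifti(maps.cbf_mean, maps.affine, outdir / "cbf_mean.nii.gz")
    write_nifti(maps.mask.astype(np.float32), maps.affine, outdir / "mask.nii.gz")
    sidecar = dict(
        subject_id=maps.subject_id,
        plds=list(maps.params.plds),
        in_mask_voxels=int(maps.mask.sum()),
        defined_wd_voxels=int(np.isfinite(maps.wd).sum()),
    )
    (outdir / "provenance.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def write_table(df: pd.DataFrame, path) -> Path:
    """Tab-separated table with header, floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
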