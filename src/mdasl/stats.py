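"""Voxel-wise two-cohort statistics with FDR and cluster-extent thresholding.

A pooled-variance two-sample t-test per in-mask voxel (matching the SPM
two-sample model, no covariates), Benjamini–Hochberg adjustment over the
in-mask p-values of each map separately, connected-component clustering of
the significant voxels with a minimum extent, plus ROI extraction, Pearson
correlation and the 2x2 chi-squared demographics test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "voxelwise_ttest",
    "fdr_correct",
    "extract_clusters",
    "roi_mean",
    "pearson_correlation",
    "chi_squared_2x2",
    "GroupComparison",
    "GroupComparisonResults",
]

log = logging.getLogger("mdasl")

CLUSTER_COLUMNS = [
    "cluster_id", "n_voxels", "peak_x_mm", "peak_y_mm", "peak_z_mm",
    "peak_t", "min_q", "sign",
]


@dataclass
class StatMap:
    """Voxel-wise test results: t, two-tailed p, BH-adjusted p (q)."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    df: int
    mask: np.ndarray
    affine: np.ndarray


def voxelwise_ttest(maps_a, maps_b, mask, affine=None) -> StatMap:
    """Pooled-variance two-sample t-test at every in-mask voxel.

    ``maps_a``/``maps_b`` stack one volume per subject on the first axis.
    Voxels undefined (NaN) in any subject are dropped from the mask for this
    test; zero pooled variance yields t=0, p=1 (flagged in the log).  The
    BH-adjusted map ``q`` is filled in by :func:`fdr_correct`.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group volume shapes differ")
    mask = np.asarray(mask, dtype=bool)
    defined = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    test_mask = mask & defined
    df = a.shape[0] + b.shape[0] - 2
    t = np.full(mask.shape, np.nan)
    p = np.full(mask.shape, np.nan)
    av, bv = a[:, test_mask], b[:, test_mask]
    tt = sps.ttest_ind(av, bv, axis=0, equal_var=True)
    tvals, pvals = np.asarray(tt.statistic), np.asarray(tt.pvalue)
    degenerate = ~np.isfinite(tvals)
    if degenerate.any():
        log.info("voxelwise_ttest: %d voxels with zero pooled variance (p set to 1)",
                 int(degenerate.sum()))
        tvals = np.where(degenerate, 0.0, tvals)
        pvals = np.where(degenerate, 1.0, pvals)
    t[test_mask], p[test_mask] = tvals, pvals
    q = np.full(mask.shape, np.nan)
    qv, _ = fdr_correct(pvals)
    q[test_mask] = qv
    if affine is None:
        affine = np.eye(4)
    return StatMap(t=t, p=p, q=q, df=df, mask=test_mask, affine=np.asarray(affine))


def fdr_correct(p_values, q_level: float = 0.05):
    """Benjamini–Hochberg step-up over one map's in-mask p-values.

    Returns (adjusted p-values, significance mask); significant means
    adjusted p < ``q_level``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), alpha=q_level, method="fdr_bh")
    q = q.reshape(p.shape)
    return q, q < q_level


def _structure(connectivity: int):
    try:
        rank = {6: 1, 18: 2, 26: 3}[int(connectivity)]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


def extract_clusters(sig_mask, stat_map: StatMap, extent: int = 100,
                     connectivity: int = 18) -> pd.DataFrame:
    """Connected components of the significance mask, filtered by extent.

    Components smaller than ``extent`` voxels are dropped.  Per surviving
    cluster: voxel count, peak (maximal |t|, ties broken by smallest linear
    index) reported in mm through the affine, the peak t, the smallest
    adjusted p in the cluster, and the effect sign at the peak.
    """
    if extent < 1:
        raise ValueError("extent must be >= 1")
    sig = np.asarray(sig_mask, dtype=bool)
    labels, n = ndimage.label(sig, structure=_structure(connectivity))
    rows = []
    absT = np.abs(np.nan_to_num(stat_map.t))
    cid = 0
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < extent:
            continue
        cid += 1
        comp_abs = np.where(comp, absT, -np.inf)
        # argmax on the flattened array takes the first (smallest linear
        # index) maximum, the documented tie-break
        peak_flat = int(np.argmax(comp_abs))
        peak_idx = np.unravel_index(peak_flat, sig.shape)
        peak_mm = (stat_map.affine @ np.array([*peak_idx, 1.0]))[:3]
        peak_t = float(stat_map.t[peak_idx])
        rows.append(dict(
            cluster_id=cid,
            n_voxels=size,
            peak_x_mm=float(peak_mm[0]),
            peak_y_mm=float(peak_mm[1]),
            peak_z_mm=float(peak_mm[2]),
            peak_t=peak_t,
            min_q=float(np.nanmin(np.where(comp, stat_map.q, np.nan))),
            sign="increase" if peak_t > 0 else "decrease",
        ))
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def roi_mean(volume, roi_mask) -> float:
    """Mean of the defined (finite) voxels inside the ROI."""
    vol = np.asarray(volume, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    vals = vol[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no defined voxels")
    return float(vals.mean())


def pearson_correlation(x, y):
    """Sample Pearson r with its two-tailed p (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def chi_squared_2x2(table):
    """Pearson chi-squared on a 2x2 count table, no continuity correction."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


class GroupComparison:
    """Two-cohort voxel-wise comparison model for one parameter map.

    Built from per-subject volumes (group A stacked against group B on a
    shared mask); ``fit`` runs the pooled t-test, per-map BH correction and
    cluster-extent thresholding.
    """

    def __init__(self, maps_a, maps_b, mask, affine=None, param_name="map"):
        self.maps_a = np.asarray(maps_a, dtype=float)
        self.maps_b = np.asarray(maps_b, dtype=float)
        self.mask = np.asarray(mask, dtype=bool)
        self.affine = np.eye(4) if affine is None else np.asarray(affine)
        self.param_name = param_name

    @classmethod
    def from_results(cls, results_a, results_b, param_name: str):
        """Stack one quantified map per subject from two lists of
        :class:`~mdasl.quantify.PerfusionResults`."""
        maps_a = np.stack([r.map_for(param_name) for r in results_a])
        maps_b = np.stack([r.map_for(param_name) for r in results_b])
        mask = np.logical_and.reduce([r.mask for r in results_a + results_b])
        return cls(maps_a, maps_b, mask, results_a[0].affine, param_name)

    def fit(self, q_level: float = 0.05, extent: int = 100,
            connectivity: int = 18) -> "GroupComparisonResults":
        stat = voxelwise_ttest(self.maps_a, self.maps_b, self.mask, self.affine)
        sig = np.zeros(self.mask.shape, dtype=bool)
        inm = stat.mask
        sig[inm] = stat.q[inm] < q_level
        clusters = extract_clusters(sig, stat, extent, connectivity)
        return GroupComparisonResults(
            stat_map=stat, sig_mask=sig, clusters=clusters,
            q_level=q_level, extent=extent, connectivity=connectivity,
            param_name=self.param_name,
            n_a=self.maps_a.shape[0], n_b=self.maps_b.shape[0],
        )


@dataclass
class GroupComparisonResults:
    """Fitted group comparison: stat maps, significance mask, cluster table."""

    stat_map: StatMap
    sig_mask: np.ndarray
    clusters: pd.DataFrame
    q_level: float
    extent: int
    connectivity: int
    param_name: str
    n_a: int
    n_b: int

    def cluster_roi_mask(self, cluster_id: int) -> np.ndarray:
        """Voxel mask of one surviving cluster (for ROI extraction)."""
        labels, _ = ndimage.label(self.sig_mask, structure=_structure(self.connectivity))
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, labels.max() + 1))
        keep = [i + 1 for i, s in enumerate(sizes) if s >= self.extent]
        if not (1 <= cluster_id <= len(keep)):
            raise KeyError(f"no cluster {cluster_id}")
        return labels == keep[cluster_id - 1]

    def summary(self) -> str:
        s = self.stat_map
        lines = [
            f"Two-sample comparison — {self.param_name} "
            f"(n={self.n_a} vs n={self.n_b}, df={s.df})",
            f"  voxels tested: {int(s.mask.sum())}",
            f"  FDR q<{self.q_level:g}, extent >= {self.extent} voxels, "
            f"{self.connectivity}-connectivity",
            f"  significant voxels: {int(self.sig_mask.sum())}, "
            f"surviving clusters: {len(self.clusters)}",
        ]
        if len(self.clusters):
            lines.append(self.clusters.to_string(index=False,
                                                 float_format=lambda v: f"{v:.6g}"))
        return "\n".join(lines)
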