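"""Group statistics: pooled t, BH, clustering, correlation, chi-squared.

Each core operation is checked against an independent brute-force oracle
written here (step-up BH, flood fill, pooled-t and product-moment formulas).
"""

import numpy as np
import pytest
from scipy import stats as sps

from mdasl import (voxelwise_ttest, fdr_correct, extract_clusters, roi_mean,
                   pearson_correlation, chi_squared_2x2, GroupComparison)
from mdasl.stats import StatMap


# ---------------------------------------------------------------- oracles
def pooled_t_oracle(a, b):
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
           / (na + nb - 2))
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


def bh_oracle(p, q=0.05):
    """Step-up rule plus adjusted p's, straight from the definitions."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresh)[0]
    k = below.max() + 1 if below.size else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, ranked[i] * m / (i + 1))
        adj[order[i]] = running
    return adj, reject


def flood_fill_oracle(mask, connectivity=18):
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                n = abs(di) + abs(dj) + abs(dk)
                if n == 0:
                    continue
                if (connectivity == 6 and n > 1) or (connectivity == 18 and n > 2):
                    continue
                offsets.append((di, dj, dk))
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for idx in np.argwhere(mask):
        if labels[tuple(idx)]:
            continue
        nxt += 1
        stack = [tuple(idx)]
        labels[tuple(idx)] = nxt
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                q = (i + di, j + dj, k + dk)
                if all(0 <= q[d] < mask.shape[d] for d in range(3)) \
                        and mask[q] and not labels[q]:
                    labels[q] = nxt
                    stack.append(q)
    return labels


# ----------------------------------------------------------------- tests
class TestVoxelwiseTTest:
    def test_matches_pooled_oracle_to_1e12(self, rng):
        a = rng.normal(0, 1, (5, 1, 1, 1))
        b = rng.normal(0.5, 2, (5, 1, 1, 1))
        sm = voxelwise_ttest(a, b, np.ones((1, 1, 1), bool))
        t, p = pooled_t_oracle(a.ravel(), b.ravel())
        assert sm.t[0, 0, 0] == pytest.approx(t, abs=1e-12)
        assert sm.p[0, 0, 0] == pytest.approx(p, abs=1e-12)

    def test_identical_groups_null(self, rng):
        a = rng.normal(size=(4, 3, 3, 3))
        sm = voxelwise_ttest(a, a.copy(), np.ones((3, 3, 3), bool))
        np.testing.assert_allclose(sm.t[sm.mask], 0, atol=1e-12)
        np.testing.assert_allclose(sm.p[sm.mask], 1, atol=1e-12)

    def test_df_from_group_sizes(self, rng):
        a = rng.normal(size=(21, 2, 2, 2))
        b = rng.normal(size=(24, 2, 2, 2))
        assert voxelwise_ttest(a, b, np.ones((2, 2, 2), bool)).df == 43

    def test_nan_voxels_dropped_and_zero_variance_flagged(self, rng):
        a = rng.normal(size=(4, 2, 2, 2))
        b = rng.normal(size=(4, 2, 2, 2))
        a[2, 0, 0, 0] = np.nan
        a[:, 1, 1, 1] = 5.0
        b[:, 1, 1, 1] = 5.0
        sm = voxelwise_ttest(a, b, np.ones((2, 2, 2), bool))
        assert not sm.mask[0, 0, 0]
        assert sm.p[1, 1, 1] == 1.0 and sm.t[1, 1, 1] == 0.0

    def test_q_never_below_p(self, rng):
        a = rng.normal(size=(6, 4, 4, 4))
        b = rng.normal(0.3, 1, size=(6, 4, 4, 4))
        sm = voxelwise_ttest(a, b, np.ones((4, 4, 4), bool))
        assert np.all(sm.q[sm.mask] >= sm.p[sm.mask] - 1e-12)


class TestFDR:
    def test_all_ones_nothing_significant(self):
        q, sig = fdr_correct(np.ones(50))
        assert not sig.any()

    def test_single_p_identity(self):
        q, sig = fdr_correct([0.01])
        assert q[0] == pytest.approx(0.01)
        assert sig[0]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=100)
        p[rng.choice(100, 10, replace=False)] = 1e-6
        q, sig = fdr_correct(p, 0.05)
        adj, reject = bh_oracle(p, 0.05)
        np.testing.assert_allclose(q, adj, atol=1e-12)
        # the step-up rejection set matches thresholding adjusted p's here
        np.testing.assert_array_equal(sig, reject)

    def test_oracle_equivalence_large_instance(self):
        rng = np.random.default_rng(99)
        p = np.concatenate([rng.uniform(size=9000),
                            rng.uniform(0, 1e-4, size=1000)])
        adj, _ = bh_oracle(p)
        q, _ = fdr_correct(p)
        np.testing.assert_allclose(q, adj, atol=1e-12)

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([])
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])


def _statmap_for(mask_shape, t, q=None, affine=None):
    q = np.zeros(mask_shape) if q is None else q
    return StatMap(t=t, p=np.zeros(mask_shape), q=q, df=10,
                   mask=np.ones(mask_shape, bool),
                   affine=np.eye(4) if affine is None else affine)


class TestClusters:
    def test_empty_mask_empty_table(self):
        sm = _statmap_for((5, 5, 5), np.zeros((5, 5, 5)))
        assert len(extract_clusters(np.zeros((5, 5, 5), bool), sm, 10)) == 0

    def test_extent_filter_keeps_large_blob_only(self):
        sig = np.zeros((20, 20, 8), bool)
        sig[1:11, 1:6, 1:4] = True  # 150 voxels
        sig[14:19, 8:13, 5:7] = True  # 50 voxels
        t = np.where(sig, 3.0, 0.0)
        t[2, 2, 2] = 7.0
        table = extract_clusters(sig, _statmap_for(sig.shape, t), extent=100)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.n_voxels == 150
        assert row.peak_t == 7.0
        assert row.sign == "increase"

    def test_peak_coordinate_uses_affine(self):
        sig = np.zeros((6, 6, 6), bool)
        sig[2:5, 2:5, 2:5] = True
        t = np.zeros((6, 6, 6))
        t[3, 4, 2] = -9.0
        aff = np.diag([3.44, 3.44, 5.0, 1.0])
        table = extract_clusters(sig, _statmap_for(sig.shape, t, affine=aff), 1)
        row = table.iloc[0]
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == \
            (pytest.approx(3 * 3.44), pytest.approx(4 * 3.44), pytest.approx(10.0))
        assert row.sign == "decrease"

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labelling_matches_flood_fill_oracle(self, connectivity, rng):
        sig = rng.uniform(size=(12, 12, 10)) < 0.3
        t = rng.normal(size=sig.shape)
        table = extract_clusters(sig, _statmap_for(sig.shape, t), extent=1,
                                 connectivity=connectivity)
        oracle = flood_fill_oracle(sig, connectivity)
        sizes = sorted(np.bincount(oracle.ravel())[1:])
        assert sorted(table.n_voxels) == sizes

    def test_voxel_count_conservation(self, rng):
        sig = rng.uniform(size=(15, 15, 10)) < 0.25
        sm = _statmap_for(sig.shape, rng.normal(size=sig.shape))
        table = extract_clusters(sig, sm, extent=5)
        oracle = flood_fill_oracle(sig, 18)
        sizes = np.bincount(oracle.ravel())[1:]
        dropped = sizes[sizes < 5].sum()
        assert table.n_voxels.sum() + dropped == sig.sum()


class TestROIMean:
    def test_constant_and_two_voxel(self):
        vol = np.full((4, 4, 4), 3.5)
        assert roi_mean(vol, np.ones((4, 4, 4), bool)) == 3.5
        vol2 = np.zeros((2, 2, 2))
        roi = np.zeros((2, 2, 2), bool)
        vol2[0, 0, 0], vol2[1, 1, 1] = 10, 20
        roi[0, 0, 0] = roi[1, 1, 1] = True
        assert roi_mean(vol2, roi) == 15

    def test_undefined_voxels_excluded_and_empty_errors(self):
        vol = np.full((3, 3, 3), np.nan)
        roi = np.ones((3, 3, 3), bool)
        vol[0, 0, 0] = 4.0
        assert roi_mean(vol, roi) == 4.0
        with pytest.raises(ValueError):
            roi_mean(np.full((3, 3, 3), np.nan), roi)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(1.0, 8.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_product_moment_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        t_oracle = r_oracle * np.sqrt((4 - 2) / (1 - r_oracle**2))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 2)
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2])


class TestChiSquared:
    def test_reference_gender_table(self):
        # closed-form oracle N(ad-bc)^2/(r1 r2 c1 c2) evaluated beforehand:
        # 45*51^2/(21*24*19*26) = 0.47010555234239443, p = 0.4929386...
        chi2, p = chi_squared_2x2([[10, 11], [9, 15]])
        assert chi2 == pytest.approx(0.47010555234239443, rel=1e-12)
        assert p == pytest.approx(0.493, abs=5e-4)

    def test_proportional_table_null(self):
        chi2, p = chi_squared_2x2([[10, 10], [20, 20]])
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_2x2([[0, 0], [5, 5]])


class TestGroupComparison:
    def test_planted_difference_detected(self, rng):
        shape = (10, 10, 8)
        mask = np.ones(shape, bool)
        a = rng.normal(0, 1, (8,) + shape)
        b = rng.normal(0, 1, (8,) + shape)
        a[:, 2:6, 2:6, 2:5] += 4.0
        fit = GroupComparison(a, b, mask).fit(q_level=0.05, extent=10)
        assert len(fit.clusters) >= 1
        assert fit.clusters.iloc[0].sign == "increase"
        roi = fit.cluster_roi_mask(1)
        assert roi.sum() == fit.clusters.iloc[0].n_voxels
        assert "surviving clusters" in fit.summary()
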