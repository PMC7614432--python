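"""Statistics: ROI Spearman, Bonferroni, Wilcoxon (vs sign-enumeration
oracle), spatial Pearson, paired t, voxelwise ANOVA, and BH-FDR (vs
brute-force step-up oracle)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import lagcvr as lc
from lagcvr import stats as lstats


def make_lagmap(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return lc.LagMap(
        lag_s=np.where(valid, values, np.nan),
        peak_r=np.where(valid, 0.9, np.nan),
        valid=valid,
        at_boundary=np.zeros(values.shape, bool),
        degenerate=np.zeros(values.shape, bool),
    )


def make_cvrmap(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return lc.CvrMap(
        cvr=np.where(valid, values, np.nan),
        delay_s=np.zeros(values.shape),
        fit_r=np.where(valid, 0.9, np.nan),
        valid=valid,
    )


class TestRoiSpearman:
    def test_monotone_relationship_gives_one(self):
        rng = np.random.default_rng(0)
        lag_vals = rng.normal(size=(5, 5, 2))
        cvr_vals = np.exp(lag_vals)  # strictly monotone transform
        roi = np.ones((5, 5, 2), dtype=bool)
        res = lstats.roi_spearman(make_lagmap(lag_vals), make_cvrmap(cvr_vals),
                                  roi)
        assert res.r == pytest.approx(1.0)
        assert res.n_voxels == 50

    def test_monotone_invariance(self):
        rng = np.random.default_rng(1)
        lag_vals = rng.normal(size=(6, 6, 2))
        cvr_vals = rng.normal(size=(6, 6, 2))
        roi = np.ones((6, 6, 2), dtype=bool)
        base = lstats.roi_spearman(make_lagmap(lag_vals),
                                   make_cvrmap(cvr_vals), roi)
        warped = lstats.roi_spearman(make_lagmap(np.tanh(lag_vals) * 3),
                                     make_cvrmap(cvr_vals**3), roi)
        assert base.r == pytest.approx(warped.r)

    def test_joint_validity_masking(self):
        lag_vals = np.arange(24, dtype=float).reshape(4, 3, 2)
        cvr_vals = lag_vals.copy()
        lag_valid = np.ones_like(lag_vals, dtype=bool)
        lag_valid[0] = False
        cvr_valid = np.ones_like(cvr_vals, dtype=bool)
        cvr_valid[3] = False
        res = lstats.roi_spearman(
            make_lagmap(lag_vals, lag_valid),
            make_cvrmap(cvr_vals, cvr_valid),
            np.ones_like(lag_valid),
        )
        assert res.n_voxels == 12  # only jointly valid voxels count

    def test_all_tied_values_flagged(self):
        lag_vals = np.arange(24, dtype=float).reshape(4, 3, 2)
        res = lstats.roi_spearman(make_lagmap(lag_vals),
                                  make_cvrmap(np.ones((4, 3, 2))),
                                  np.ones((4, 3, 2), bool))
        assert not res.ok

    def test_too_few_voxels_flagged(self):
        roi = np.zeros((4, 3, 2), dtype=bool)
        roi[0, 0, 0] = True
        res = lstats.roi_spearman(make_lagmap(np.ones((4, 3, 2))),
                                  make_cvrmap(np.ones((4, 3, 2))), roi)
        assert not res.ok


class TestBonferroni:
    def test_six_roi_threshold(self):
        assert lstats.bonferroni_alpha(0.05, 6) == pytest.approx(0.0083, abs=5e-5)

    @pytest.mark.parametrize("family,n,expected",
                             [(0.05, 1, 0.05), (0.10, 5, 0.02)])
    def test_simple_cases(self, family, n, expected):
        assert lstats.bonferroni_alpha(family, n) == pytest.approx(expected)


def wilcoxon_exact_oracle(values):
    """Two-sided signed-rank p by full enumeration of the 2^n sign
    assignments (no ties, no zeros)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = sps.rankdata(np.abs(values))
    w_obs = ranks[values > 0].sum()
    mean_w = n * (n + 1) / 4
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append((ranks * np.asarray(signs)).sum())
    dist = np.asarray(dist)
    tail = np.mean(np.abs(dist - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return tail


class TestWilcoxon:
    def test_all_positive_small_sample_exact(self):
        p, sig = lstats.group_wilcoxon_vs_zero(np.arange(1.0, 11.0), 0.0083)
        assert p == pytest.approx(2 / 2**10)
        assert sig

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0.1, 0.3, size=11)
        p, _ = lstats.group_wilcoxon_vs_zero(values, 0.05)
        assert p == pytest.approx(wilcoxon_exact_oracle(values), abs=1e-10)

    def test_symmetric_pairs_not_significant(self):
        values = np.array([0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.4, -0.4])
        p, sig = lstats.group_wilcoxon_vs_zero(values, 0.05)
        assert p > 0.9
        assert not sig

    def test_all_zero_convention(self):
        p, sig = lstats.group_wilcoxon_vs_zero(np.zeros(10), 0.05)
        assert p == 1.0 and not sig

    def test_strict_significance(self):
        values = np.arange(1.0, 11.0)
        p, sig = lstats.group_wilcoxon_vs_zero(values, p_alpha := 2 / 2**10)
        assert p == pytest.approx(p_alpha) and not sig  # p == alpha: not below


class TestSpatialPearson:
    def test_self_correlation(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(5, 4, 3))
        m = make_lagmap(vals)
        assert lstats.spatial_pearson(m, m, np.ones(vals.shape, bool)) == \
            pytest.approx(1.0)

    def test_negation(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 4, 3))
        r = lstats.spatial_pearson(make_lagmap(vals), make_lagmap(-vals),
                                   np.ones(vals.shape, bool))
        assert r == pytest.approx(-1.0)

    def test_shared_lag_field_correlates_across_phantoms(self, anatomy):
        maps = []
        for seed in (41, 42):
            truth = lc.make_ground_truth(anatomy, noise_sd=10.0 / 3.0,
                                         seed=seed)
            if seed == 42:
                # same tau field, independent realisation
                truth.lag_field = lc.make_ground_truth(
                    anatomy, noise_sd=10.0 / 3.0, seed=41
                ).lag_field
            bold = lc.simulate_rest_bold(anatomy, truth)
            ref = lc.reference_timeseries(bold, anatomy.gm_mask,
                                          exclude_mask=anatomy.lesion_mask)
            maps.append(lc.compute_lag_map(bold, ref))
        r = lstats.spatial_pearson(maps[0], maps[1],
                                   anatomy.gm_mask & ~anatomy.lesion_mask)
        assert r > 0.8

    def test_too_few_voxels_rejected(self):
        vals = np.ones((2, 2, 1))
        with pytest.raises(ValueError):
            lstats.spatial_pearson(make_lagmap(vals), make_lagmap(vals),
                                   np.ones((2, 2, 1), bool))


class TestPairedTtest:
    def test_no_change_gives_half(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert lstats.paired_onetailed_ttest(v, v.copy()) == 0.5

    def test_direction(self):
        rng = np.random.default_rng(4)
        v1 = rng.normal(1.0, 0.05, size=12)
        v2 = v1 - 0.5 + rng.normal(0, 0.01, size=12)
        assert lstats.paired_onetailed_ttest(v1, v2, "less") < 1e-3
        assert lstats.paired_onetailed_ttest(v1, v2, "greater") > 0.999

    def test_hand_computed_five_pairs(self):
        v1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v2 = np.array([0.8, 1.7, 2.9, 3.6, 4.5])
        d = v2 - v1
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        expected = sps.t.cdf(t, df=4)
        assert lstats.paired_onetailed_ttest(v1, v2, "less") == \
            pytest.approx(expected)

    def test_constant_shift_limit(self):
        v1 = np.array([1.0, 2.0, 3.0])
        # float subtraction leaves ~1e-16 jitter in the differences, so the
        # result is the near-degenerate limit rather than exactly 0/1
        assert lstats.paired_onetailed_ttest(v1, v1 - 0.3, "less") < 1e-10
        assert lstats.paired_onetailed_ttest(v1, v1 - 0.3, "greater") > 1 - 1e-10


class TestGroupAnova:
    def design(self, n_per_cell=5):
        g, t = [], []
        for gi in ("patient", "control"):
            for ti in ("v1", "v2"):
                g += [gi] * n_per_cell
                t += [ti] * n_per_cell
        return g, t

    def test_identical_cells_give_null_f(self):
        shape = (4, 4, 2)
        base = np.arange(32, dtype=float).reshape(shape)
        g, t = self.design()
        maps = [base.copy() for _ in range(20)]
        res = lstats.voxelwise_group_anova(maps, g, t)
        np.testing.assert_allclose(res.f_group[res.analysis_mask], 0.0)
        np.testing.assert_allclose(res.p_group[res.analysis_mask], 1.0)
        np.testing.assert_allclose(res.p_interaction[res.analysis_mask], 1.0)

    def test_reduces_to_squared_t_on_balanced_two_group(self):
        """With no timepoint effect, the group F equals the squared
        two-sample t on cell-collapsed data (constructed case: timepoint
        has no effect and the design is balanced)."""
        rng = np.random.default_rng(6)
        shape = (3, 3, 1)
        g, t = self.design(n_per_cell=4)
        base = rng.normal(size=(16,) + shape)
        offset = np.where(np.asarray(g) == "patient", 0.7, 0.0)
        maps = [base[i] + offset[i] for i in range(16)]
        res = lstats.voxelwise_group_anova(maps, g, t)
        Y = np.stack(maps).reshape(16, -1)
        is_pat = np.asarray(g) == "patient"
        # oracle: OLS F for the group column via statsmodels on one voxel
        import statsmodels.api as sm

        gi = np.where(is_pat, 1.0, -1.0)
        ti = np.where(np.asarray(t) == "v2", 1.0, -1.0)
        X = sm.add_constant(np.column_stack([gi, ti, gi * ti]))
        for v in range(3):
            fit = sm.OLS(Y[:, v], X).fit()
            f_ref = fit.f_test("x1 = 0").fvalue
            assert res.f_group.reshape(-1)[v] == pytest.approx(float(f_ref))

    def test_detects_constructed_group_offset_after_fdr(self):
        rng = np.random.default_rng(7)
        shape = (6, 6, 3)
        region = np.zeros(shape, bool)
        region[:3, :3, :] = True
        g, t = self.design()
        maps = []
        for gi, ti in zip(g, t):
            m = rng.normal(0, 0.1, shape)
            if gi == "patient":
                m[region] += 0.5
            maps.append(m)
        res = lstats.voxelwise_group_anova(maps, g, t, q=0.1)
        assert res.sig_group[region].mean() > 0.9
        assert res.sig_group[~region].mean() < 0.2

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        shape = (8, 8, 4)
        g, t = self.design()
        maps = [rng.normal(0, 0.1, shape) for _ in range(20)]
        res = lstats.voxelwise_group_anova(maps, g, t)
        pooled = np.concatenate([
            res.p_group[res.analysis_mask],
            res.p_timepoint[res.analysis_mask],
            res.p_interaction[res.analysis_mask],
        ])
        assert sps.kstest(pooled, "uniform").pvalue > 0.01

    def test_partial_validity_handled_per_pattern(self):
        rng = np.random.default_rng(9)
        shape = (4, 4, 2)
        g, t = self.design()
        maps, valids = [], []
        for i in range(20):
            m = rng.normal(0, 0.1, shape)
            v = np.ones(shape, dtype=bool)
            if i == 0:
                v[0, 0, 0] = False  # one subject missing one voxel
            m[~v] = np.nan
            maps.append(m)
        res = lstats.voxelwise_group_anova(maps, g, t, min_valid_fraction=0.8)
        assert res.analysis_mask[0, 0, 0]  # 19/20 valid still analysed
        assert np.isfinite(res.p_group[0, 0, 0])

    def test_empty_cell_rejected(self):
        maps = [np.zeros((2, 2, 1))] * 6
        with pytest.raises(ValueError):
            lstats.voxelwise_group_anova(
                maps, ["a"] * 6, ["v1", "v2"] * 3
            )


def fdr_oracle(p, q):
    """Brute-force BH step-up: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = p.size
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestFdr:
    def test_step_up_small_example(self):
        mask = lstats.fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), q=0.1)
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_all_ones_reject_none(self):
        assert not lstats.fdr_bh(np.ones(8), 0.1).any()

    def test_all_zeros_reject_all(self):
        assert lstats.fdr_bh(np.zeros(8), 0.1).all()

    def test_empty_input(self):
        assert lstats.fdr_bh(np.array([]), 0.1).size == 0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
           st.sampled_from([0.05, 0.1, 0.2]))
    def test_matches_brute_force_step_up(self, p_list, q):
        p = np.asarray(p_list)
        np.testing.assert_array_equal(lstats.fdr_bh(p, q), fdr_oracle(p, q))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_bh_rejects_at_least_bonferroni(self, p_list):
        p = np.asarray(p_list)
        q = 0.1
        bonf = p <= q / p.size
        bh = lstats.fdr_bh(p, q)
        assert np.all(bh[bonf])

    def test_nan_entries_never_rejected(self):
        p = np.array([0.001, np.nan, 0.002])
        mask = lstats.fdr_bh(p, 0.1)
        assert not mask[1] and mask[0] and mask[2]
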