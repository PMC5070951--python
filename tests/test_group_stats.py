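"""Group-level statistics: contrasts, FDR, masks, power analysis."""

import numpy as np
import pytest
from scipy import stats as sps

from crossfreq.group_stats import (
    ParcelMeta,
    collapse_adjacency,
    connection_density,
    effect_size_mask,
    equalize_trials,
    fdr_mask,
    leave_one_out_mask,
    load_condition_test,
    mean_condition_test,
    minimal_detectable_effect,
    plv_amplitude_effect_correlation,
)


class TestEqualizeTrials:
    def test_min_rule(self):
        sel = equalize_trials([300, 280, 310], seed=0)
        assert all(len(s) == 280 for s in sel)
        assert all(len(np.unique(s)) == len(s) for s in sel)

    def test_equal_counts_full_size(self):
        sel = equalize_trials([50, 50], seed=0)
        assert all(len(s) == 50 for s in sel)

    def test_reproducible(self):
        a = equalize_trials([100, 80, 90], seed=7)
        b = equalize_trials([100, 80, 90], seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            equalize_trials([10, 0, 5])


class TestCollapseAdjacency:
    @staticmethod
    def _meta(fine_to_coarse, n_coarse):
        n = len(fine_to_coarse)
        return ParcelMeta(
            fine_to_coarse=np.asarray(fine_to_coarse),
            coarse_to_system=np.zeros(n_coarse, dtype=int),
            fidelity=np.ones(n),
            cross_talk=np.full(n, 0.1),
            spread=np.full(n, 0.1),
            excluded=np.zeros(n, dtype=bool),
        )

    def test_constant_matrix_preserved(self):
        meta = self._meta([0, 0, 1, 1], 2)
        fine = np.full((4, 4), 0.5)
        coarse = collapse_adjacency(fine, meta)
        assert np.allclose(coarse, 0.5)

    def test_identity_mapping(self):
        meta = self._meta([0, 1, 2], 3)
        fine = np.arange(9.0).reshape(3, 3)
        assert np.allclose(collapse_adjacency(fine, meta), fine)

    def test_block_mean(self):
        meta = self._meta([0, 0, 1, 1], 2)
        fine = np.zeros((4, 4))
        # off-diagonal block between coarse 0 and coarse 1: values 0.1 / 0.3
        fine[0, 2], fine[0, 3], fine[1, 2], fine[1, 3] = 0.1, 0.3, 0.3, 0.1
        coarse = collapse_adjacency(fine, meta)
        assert coarse[0, 1] == pytest.approx(0.2)

    def test_excluded_parcels_dropped(self):
        meta = self._meta([0, 0, 1, 1], 2)
        meta.excluded[1] = True
        fine = np.zeros((4, 4))
        fine[0, 2] = fine[0, 3] = 0.4
        fine[1, 2] = fine[1, 3] = 100.0  # excluded parcel's rows must not count
        coarse = collapse_adjacency(fine, meta)
        assert coarse[0, 1] == pytest.approx(0.4)


class TestFdrMask:
    def test_expected_fp_removes_largest_significant_p(self):
        p = np.array([0.001, 0.002, 0.04, 0.2, 0.9, 0.6, 0.7, 0.8, 0.55, 0.45,
                      0.65, 0.75, 0.85, 0.95, 0.35, 0.25, 0.15, 0.5, 0.3, 0.1])
        mask = fdr_mask(p, alpha=0.05, method="expected_fp")
        # significant: 0.001, 0.002, 0.04; ceil(0.05*20)=1 removed -> 0.04 out
        assert mask[0] and mask[1] and not mask[2]

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 50) ** 2
        assert np.array_equal(fdr_mask(p, 0.05, "bh"),
                              multipletests(p, 0.05, method="fdr_bh")[0])


class TestMeanCondition:
    def test_identical_conditions_not_significant(self, rng):
        vals = rng.uniform(0, 1, size=(12, 20))
        g = mean_condition_test(vals, vals.copy())
        assert g.n_significant == 0
        # zero-variance differences flagged indeterminate
        assert np.all(np.isnan(g.effect_size))

    def test_planted_effect_detected(self, rng):
        base = rng.normal(0.2, 0.02, size=(12, 30))
        ret = base + rng.normal(0.0, 0.02, size=(12, 30))
        ret[:, 5] += 0.08  # d ~ 3 at edge 5
        g = mean_condition_test(ret, base, fdr_method="bh")
        assert g.significant[5] and g.sign[5] == 1
        assert g.tail(1)[5]

    def test_t_statistic_matches_paired_oracle(self, rng):
        ret = rng.uniform(0, 1, size=(12, 1))
        bl = rng.uniform(0, 1, size=(12, 1))
        g = mean_condition_test(ret, bl)
        t_oracle, p_oracle = sps.ttest_rel(ret[:, 0], bl[:, 0])
        t_mine = g.effect_size[0] * np.sqrt(12)
        assert t_mine == pytest.approx(t_oracle, abs=1e-10)
        assert g.p_value[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_effect_antisymmetric_under_swap(self, rng):
        ret = rng.uniform(0, 1, size=(8, 10))
        bl = rng.uniform(0, 1, size=(8, 10))
        a = mean_condition_test(ret, bl).effect_size
        b = mean_condition_test(bl, ret).effect_size
        assert np.allclose(a, -b)


class TestLoadCondition:
    def test_monotone_increase_gives_unit_rho(self):
        vals = np.tile(np.linspace(0.1, 0.6, 6)[None, :, None], (12, 1, 3))
        vals = vals + np.random.default_rng(0).normal(0, 1e-6, vals.shape)
        g = load_condition_test(vals, fdr_method="bh")
        # tied load ranks across subjects cap pooled rho just below 1
        assert np.all(g.effect_size > 0.98)
        assert np.all(g.significant)

    def test_matches_spearman_oracle(self, rng):
        vals = rng.uniform(0, 1, size=(12, 6, 4))
        g = load_condition_test(vals)
        loads = np.repeat(np.arange(1, 7)[None, :], 12, axis=0).ravel()
        for e in range(4):
            rho, p = sps.spearmanr(vals[:, :, e].reshape(-1), loads)
            assert g.effect_size[e] == pytest.approx(rho, abs=1e-10)
            assert g.p_value[e] == pytest.approx(p, rel=1e-6)

    def test_shuffled_loads_near_alpha(self, rng):
        # uncorrelated data: raw p < alpha in ~ alpha of edges
        vals = rng.uniform(0, 1, size=(12, 6, 400))
        g = load_condition_test(vals)
        frac_raw = np.mean(g.p_value < 0.05)
        assert frac_raw < 0.10


class TestDensityAndMasks:
    @staticmethod
    def _graph(n_edges, sig_idx, effects=None):
        eff = np.zeros(n_edges) if effects is None else np.asarray(effects, float)
        sig = np.zeros(n_edges, dtype=bool)
        sig[list(sig_idx)] = True
        from crossfreq.group_stats import StatGraph

        return StatGraph(eff, np.full(n_edges, 0.5), sig,
                         np.sign(eff).astype(int), n_possible=n_edges)

    def test_density_extremes(self):
        assert connection_density(self._graph(10, [])) == 0.0
        assert connection_density(self._graph(10, range(10))) == 1.0

    def test_density_arithmetic(self):
        n_possible = 148 * 147 // 2
        g = self._graph(n_possible, range(147))
        assert connection_density(g) == pytest.approx(147 / n_possible)
        assert connection_density(g) == pytest.approx(0.0135, abs=5e-4)

    def test_effect_size_mask(self):
        g = self._graph(2, [0, 1], effects=[0.8, 1.0])
        assert effect_size_mask(g, 0.9).n_significant == 1
        assert effect_size_mask(g, 0.0).n_significant == 2
        assert effect_size_mask(g, 2.0).n_significant == 0

    def test_leave_one_out_drops_outlier_driven_edge(self, rng):
        # edge 0: effect carried by one extreme subject; edge 1: homogeneous
        n_subj = 10
        diffs = rng.normal(0.0, 0.01, size=(n_subj, 2))
        diffs[:, 1] += 0.05
        diffs[0, 0] += 1.5
        diffs[1:, 0] += 0.004

        def stat(keep):
            d = diffs[keep]
            t, p = sps.ttest_1samp(d, 0.0, axis=0)
            return p

        base = self._graph(2, [0, 1])
        out = leave_one_out_mask(stat, np.arange(n_subj), base, alpha=0.05)
        assert not out.significant[0]
        assert out.significant[1]

    def test_leave_one_out_empty_base(self):
        base = self._graph(3, [])
        out = leave_one_out_mask(lambda keep: np.zeros(3), np.arange(5), base)
        assert out.n_significant == 0


class TestMinimalDetectableEffect:
    def test_cohort_of_twelve_needs_point_nine(self):
        d = minimal_detectable_effect(n=12, alpha=0.05, power=0.8,
                                      design="one_sample_t")
        assert round(d, 1) == 0.9

    def test_power_equal_alpha_gives_zero_effect(self):
        d = minimal_detectable_effect(n=12, alpha=0.05, power=0.0500001)
        assert d < 0.02

    def test_returned_effect_achieves_power_in_simulation(self, rng):
        n, alpha = 12, 0.05
        d = minimal_detectable_effect(n=n, alpha=alpha, power=0.8)
        reps = 4000
        x = rng.normal(d, 1.0, size=(reps, n))
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
        crit = sps.t.ppf(1 - alpha / 2, n - 1)
        power_emp = np.mean(np.abs(t) > crit)
        assert power_emp == pytest.approx(0.8, abs=0.03)

    def test_correlation_design_monotone_in_n(self):
        r_small = minimal_detectable_effect(n=20, design="correlation")
        r_large = minimal_detectable_effect(n=72, design="correlation")
        assert r_large < r_small
        assert 0.2 < r_large < 0.45


class TestPlvAmplitudeCorrelation:
    def test_identical_effects_significant_unity(self, rng):
        x = rng.normal(0, 1, 40)
        res = plv_amplitude_effect_correlation(x, x.copy(), n_surrogates=200, rng=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["significant"]
        assert res["signed_r2"] == pytest.approx(1.0)

    def test_matches_pearson_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        res = plv_amplitude_effect_correlation(x, y, n_surrogates=50, rng=0)
        assert res["r"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValueError):
            plv_amplitude_effect_correlation(np.ones(2), np.ones(2))
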