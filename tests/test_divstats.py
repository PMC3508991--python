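"""Gamma/CR/MCCR tests, LTT curves, interval rates, branch-length CDF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chronodiv as cd
from chronodiv.treeio import BranchingTimes, TreeError
from conftest import gamma_oracle


def random_bt(rng, n):
    ages = np.sort(rng.uniform(0.1, 20.0, n - 1))[::-1]
    return BranchingTimes(ages=ages, n=n, crown_age=float(ages[0]))


class TestGamma:
    def test_matches_hand_expanded_formula_on_comb(self, comb5):
        bt = cd.branching_times(comb5)
        res = cd.gamma_statistic(bt)
        assert res.gamma == pytest.approx(gamma_oracle([4, 3, 2, 1]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle_on_random_ages(self, seed):
        rng = np.random.default_rng(seed)
        bt = random_bt(rng, int(rng.integers(4, 40)))
        res = cd.gamma_statistic(bt)
        assert res.gamma == pytest.approx(gamma_oracle(bt.ages.tolist()), abs=1e-10)

    def test_p_value_conventions(self):
        rng = np.random.default_rng(1)
        res = cd.gamma_statistic(random_bt(rng, 20))
        assert res.p_value == pytest.approx(1.0 - res.p_upper)
        assert 0 <= res.p_two_sided <= 1

    def test_minimum_n_is_four(self, three_tip):
        with pytest.raises(TreeError, match="n >= 4"):
            cd.gamma_statistic(cd.branching_times(three_tip))

    def test_depends_only_on_age_multiset(self):
        # relabeling tips / changing topology while preserving node ages
        # leaves gamma unchanged
        a = cd.Chronogram.from_newick("((A:1,B:1):2,(C:2,D:2):1);")
        b = cd.Chronogram.from_newick("(((X:1,Y:1):1,Z:2):1,W:3);")
        ga = cd.gamma_statistic(cd.branching_times(a))
        gb = cd.gamma_statistic(cd.branching_times(b))
        assert sorted(cd.branching_times(a).ages) == sorted(
            cd.branching_times(b).ages
        )
        assert ga.gamma == pytest.approx(gb.gamma)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        bt = random_bt(rng, 12)
        scaled = BranchingTimes(ages=bt.ages * 3.7, n=bt.n,
                                crown_age=bt.crown_age * 3.7)
        assert cd.gamma_statistic(bt).gamma == pytest.approx(
            cd.gamma_statistic(scaled).gamma, rel=1e-9
        )


class TestMCCR:
    def test_null_shifts_below_zero_under_pruning(self):
        sim = cd.simulate_tree(cd.SimConfig(model="yule1", lambda1=0.3,
                                            n_total=20, seed=2))
        bt = cd.branching_times(cd.prune_to_sample(sim.chronogram, 15, seed=3))
        res = cd.mccr_test(bt, n_total=20, reps=200, seed=4)
        assert res.null_gammas.mean() < 0
        assert res.reps == 200
        assert 0 <= res.p_lower <= 1

    def test_large_observed_gamma_is_extreme(self):
        # a strongly tip-ward gamma (like the empirical +2.6) stays above
        # the pruning null's 95th percentile
        sim = cd.simulate_tree(cd.SimConfig(model="yule2", lambda1=0.05,
                                            lambda2=0.8, shift_time=2.0,
                                            n_total=40, seed=5))
        bt = cd.branching_times(sim.chronogram)
        obs = cd.gamma_statistic(bt).gamma
        assert obs > 1.5
        res = cd.mccr_test(bt, n_total=45, reps=200, seed=6)
        assert res.p_upper < 0.05
        assert res.outside_95

    def test_reps_floor(self, yule_tree):
        with pytest.raises(ValueError, match="reps"):
            cd.mccr_test(yule_tree.branching_times(), n_total=45, reps=50)

    def test_determinism(self, yule_tree):
        bt = yule_tree.branching_times()
        a = cd.mccr_test(bt, n_total=45, reps=100, seed=7)
        b = cd.mccr_test(bt, n_total=45, reps=100, seed=7)
        np.testing.assert_array_equal(a.null_gammas, b.null_gammas)


class TestLTT:
    def test_three_tip_steps(self, three_tip):
        curve = cd.ltt_curve(three_tip)
        np.testing.assert_allclose(curve.times, [2.0, 1.0, 0.0])
        np.testing.assert_array_equal(curve.lineage_counts, [2, 3, 3])

    def test_endpoints(self, yule_tree):
        curve = cd.ltt_curve(yule_tree.chronogram)
        n = yule_tree.chronogram.n_tips
        assert curve.at_age(0.0) == n
        assert curve.at_age(curve.times[0]) == 2
        assert np.all(np.diff(curve.lineage_counts) >= 0)

    def test_log_slope_estimates_lambda(self):
        # regression of ln(lineages) on elapsed time ~ lambda on large trees
        lam, slopes = 0.3, []
        for s in range(60):
            bt = cd.simulate_tree(
                cd.SimConfig(model="yule1", lambda1=lam, n_total=200, seed=s)
            ).branching_times()
            curve = cd.ltt_curve(bt)
            t = curve.times[0] - curve.times  # elapsed since crown
            slopes.append(np.polyfit(t, np.log(curve.lineage_counts), 1)[0])
        assert np.mean(slopes) == pytest.approx(lam, rel=0.1)

    def test_mltt_draws_without_replacement(self):
        base = cd.simulate_tree(cd.SimConfig(n_total=10, seed=8))
        sample = cd.jitter_tree_sample(base.chronogram, 12, jitter_sd=0.02, seed=9)
        curves = cd.mltt(sample, k=12, seed=10)
        assert len(curves) == 12
        crowns = sorted(c.times[0] for c in curves)
        expected = sorted(cd.branching_times(t).crown_age for t in sample)
        np.testing.assert_allclose(crowns, expected)
        with pytest.raises(ValueError):
            cd.mltt(sample, k=13)


class TestIntervalRates:
    def test_three_tip_hand_count(self, three_tip):
        r = cd.interval_rates(cd.branching_times(three_tip), delta_t=1.0)
        np.testing.assert_allclose(r.bin_edges, [2.0, 1.0, 0.0])
        np.testing.assert_array_equal(r.delta_n, [1, 0])
        np.testing.assert_array_equal(r.n_start, [2, 3])
        np.testing.assert_allclose(r.rate, [0.5, 0.0])

    @pytest.mark.parametrize("delta_t", [0.3, 0.9, 2.0, 7.0])
    def test_conservation_sum_delta_n(self, delta_t):
        for seed in range(30):
            bt = cd.simulate_tree(
                cd.SimConfig(model="yule1", lambda1=0.4,
                             n_total=int(5 + seed % 40), seed=seed)
            ).branching_times()
            r = cd.interval_rates(bt, delta_t=delta_t)
            assert r.delta_n.sum() == bt.n - 2
            assert r.n_start[0] == 2

    def test_present_anchor_also_conserves(self, yule_tree):
        bt = yule_tree.branching_times()
        r = cd.interval_rates(bt, delta_t=0.9, anchor="present")
        assert r.delta_n.sum() == bt.n - 2
        assert r.bin_edges[-1] == 0.0
        assert r.bin_edges[0] == pytest.approx(bt.crown_age)

    def test_rate_recovers_lambda(self):
        # mean per-bin rate/Ma tracks lambda in bins with >= 10 lineages
        lam, vals = 0.3, []
        for s in range(150):
            bt = cd.simulate_tree(
                cd.SimConfig(model="yule1", lambda1=lam, n_total=200, seed=s)
            ).branching_times()
            r = cd.interval_rates(bt, delta_t=0.3)
            ok = r.n_start >= 10
            vals.extend(r.rate_per_ma[ok])
        assert np.mean(vals) == pytest.approx(lam, rel=0.15)

    def test_bad_delta_t(self, yule_tree):
        with pytest.raises(ValueError):
            cd.interval_rates(yule_tree.branching_times(), delta_t=0.0)


class TestBranchLengthCDF:
    def test_cumulative_monotone_to_one(self):
        rng = np.random.default_rng(0)
        res = cd.branch_length_cdf(rng.exponential(1.0, 200))
        assert np.all(np.diff(res.cumulative_freq) >= 0)
        assert res.cumulative_freq[-1] == pytest.approx(1.0)
        assert np.all(np.diff(res.fitted_constant_cdf) >= 0)
        assert np.all(np.diff(res.fitted_variable_cdf) >= 0)
        assert len(res.class_edges) == 10

    def test_exponential_classified_constant(self):
        rng = np.random.default_rng(1)
        hits = sum(
            cd.branch_length_cdf(rng.exponential(1.0, 500)).classification
            == "constant"
            for _ in range(40)
        )
        assert hits >= 36  # >= 90%

    def test_mixture_classified_variable(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            x = np.concatenate(
                [rng.exponential(1 / 0.2, 250), rng.exponential(1 / 5.0, 250)]
            )
            hits += cd.branch_length_cdf(x).classification == "variable"
        assert hits >= 36

    def test_few_distinct_values_widen_classes(self):
        x = np.tile([1.0, 2.0, 3.0], 10)
        with pytest.warns(UserWarning, match="distinct"):
            res = cd.branch_length_cdf(x)
        assert len(res.class_edges) == 3

    def test_too_few_lengths_rejected(self):
        with pytest.raises(ValueError):
            cd.branch_length_cdf(np.ones(5))
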