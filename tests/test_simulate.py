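"""Ground-truth simulators: trees, pruning, tree samples, range histories."""

import numpy as np
import pytest
from scipy import stats

import chronodiv as cd


class TestYuleSimulator:
    def test_tip_and_node_counts(self):
        sim = cd.simulate_tree(cd.SimConfig(model="yule1", lambda1=0.2, n_total=65, seed=5))
        assert sim.chronogram.n_tips == 65
        assert len(sim.node_ages) == 64
        assert sim.chronogram.is_ultrametric()

    def test_determinism_bit_identical(self):
        cfg = cd.SimConfig(model="yule1", lambda1=0.2, n_total=30, seed=123)
        a = cd.simulate_tree(cfg).chronogram.as_newick()
        b = cd.simulate_tree(cfg).chronogram.as_newick()
        assert a == b

    def test_different_seeds_differ(self):
        a = cd.simulate_tree(cd.SimConfig(n_total=30, seed=1)).chronogram.as_newick()
        b = cd.simulate_tree(cd.SimConfig(n_total=30, seed=2)).chronogram.as_newick()
        assert a != b

    def test_internode_intervals_are_exponential(self):
        # with k lineages the interval is Exp(k*lambda): check mean and
        # variance for a few k at 1000 replicates
        lam, n, reps = 0.5, 8, 1000
        g = np.empty((reps, n - 1))
        for s in range(reps):
            bt = cd.simulate_tree(
                cd.SimConfig(model="yule1", lambda1=lam, n_total=n, seed=s)
            ).branching_times()
            g[s] = bt.internode_intervals()
        for i, k in enumerate(range(2, n + 1)):
            mean, var = g[:, i].mean(), g[:, i].var(ddof=1)
            assert mean == pytest.approx(1 / (k * lam), rel=0.12)
            assert var == pytest.approx(1 / (k * lam) ** 2, rel=0.3)

    def test_yule2_post_shift_intervals_shorter(self):
        # mean post-shift interval with k lineages ~ 1/(k*lambda2)
        lam1, lam2, shift = 0.1, 0.5, 4.0
        post = []
        for s in range(1000):
            bt = cd.simulate_tree(
                cd.SimConfig(
                    model="yule2", lambda1=lam1, lambda2=lam2,
                    shift_time=shift, n_total=12, seed=s,
                )
            ).branching_times()
            ages = np.concatenate([bt.ages, [0.0]])
            # youngest interval (k = n = 12 lineages), entirely post-shift
            # whenever the youngest node is below the shift age
            if ages[-2] < shift:
                post.append(ages[-2] - ages[-1])
        assert np.mean(post) == pytest.approx(1 / (12 * lam2), rel=0.1)

    def test_yule2_crown_always_older_than_shift(self):
        for s in range(20):
            sim = cd.simulate_tree(
                cd.SimConfig(model="yule2", lambda1=0.1, lambda2=0.5,
                             shift_time=4.0, n_total=20, seed=s)
            )
            assert sim.params["crown_age"] > 4.0


class TestBirthDeath:
    def test_conditioned_tip_count(self):
        sim = cd.simulate_tree(
            cd.SimConfig(model="birthdeath", lambda1=0.4, mu=0.1, n_total=25, seed=9)
        )
        assert sim.chronogram.n_tips == 25
        assert sim.chronogram.is_ultrametric()
        np.testing.assert_allclose(
            np.sort(cd.branching_times(sim.chronogram).ages),
            np.sort(sim.node_ages), rtol=1e-9,
        )

    def test_mu_zero_matches_yule_gamma_distribution(self):
        # birth-death with mu=0 equals the pure-birth process: two-sample
        # KS test on gamma across 500 replicates
        n, reps = 20, 500
        g_bd = np.empty(reps)
        g_y = np.empty(reps)
        for s in range(reps):
            bd = cd.simulate_tree(
                cd.SimConfig(model="birthdeath", lambda1=0.4, mu=0.0,
                             n_total=n, seed=s)
            )
            yu = cd.simulate_tree(
                cd.SimConfig(model="yule1", lambda1=0.4, n_total=n, seed=10_000 + s)
            )
            g_bd[s] = cd.gamma_statistic(bd.branching_times()).gamma
            g_y[s] = cd.gamma_statistic(yu.branching_times()).gamma
        assert stats.ks_2samp(g_bd, g_y).pvalue > 0.01


class TestPruning:
    def test_identity_when_sample_n_equals_n(self, yule_tree):
        pruned = cd.prune_to_sample(yule_tree.chronogram, yule_tree.chronogram.n_tips)
        assert cd.branching_times(pruned).ages == pytest.approx(
            cd.branching_times(yule_tree.chronogram).ages
        )

    def test_too_small_sample_rejected(self, yule_tree):
        with pytest.raises(ValueError):
            cd.prune_to_sample(yule_tree.chronogram, 2)

    def test_subset_enumeration_on_five_tips(self, comb5):
        # pruning one tip from a 5-tip comb: crown age survives iff the
        # deepest tip E is retained; check all C(5,4) subsets appear and
        # every result is a valid 4-tip chronogram
        crowns = {}
        for seed in range(200):
            p = cd.prune_to_sample(comb5, 4, seed=seed)
            kept = frozenset(p.tip_labels)
            crowns[kept] = cd.branching_times(p).crown_age
        assert len(crowns) == 5  # all C(5,4) subsets realised
        for kept, crown in crowns.items():
            if "E" in kept:
                assert crown == pytest.approx(4.0)
            else:
                assert crown == pytest.approx(3.0)

    def test_pruning_lowers_gamma_in_expectation(self):
        # incomplete sampling biases gamma downward (paired comparison)
        diffs = []
        for s in range(300):
            sim = cd.simulate_tree(
                cd.SimConfig(model="yule1", lambda1=0.3, n_total=30, seed=s)
            )
            g_full = cd.gamma_statistic(sim.branching_times()).gamma
            pruned = cd.prune_to_sample(sim.chronogram, 20, seed=s + 1)
            g_pruned = cd.gamma_statistic(cd.branching_times(pruned)).gamma
            diffs.append(g_pruned - g_full)
        assert np.mean(diffs) < 0
        assert stats.ttest_1samp(diffs, 0.0).pvalue < 0.01


class TestTreeSamples:
    def test_zero_jitter_gives_identical_copies(self, yule_tree):
        sample = cd.jitter_tree_sample(yule_tree.chronogram, 5, jitter_sd=0.0, seed=0)
        ref = cd.branching_times(yule_tree.chronogram).ages
        for t in sample:
            np.testing.assert_allclose(cd.branching_times(t).ages, ref, rtol=1e-12)

    def test_all_replicates_ultrametric(self, yule_tree):
        sample = cd.jitter_tree_sample(
            yule_tree.chronogram, 20, jitter_sd=0.1, nni_prob=0.1, seed=2
        )
        assert all(t.is_ultrametric() for t in sample)
        assert len(sample) == 20

    def test_crown_age_cv_tracks_jitter_sd(self):
        base = cd.simulate_tree(cd.SimConfig(n_total=20, lambda1=0.3, seed=6))
        sample = cd.jitter_tree_sample(base.chronogram, 400, jitter_sd=0.05, seed=7)
        crowns = np.array([cd.branching_times(t).crown_age for t in sample])
        cv = crowns.std(ddof=1) / crowns.mean()
        # crown age carries one multiplicative factor -> CV ~ jitter_sd
        assert cv == pytest.approx(0.05, rel=0.25)

    def test_simulate_tree_sample_wrapper(self):
        sim, sample = cd.simulate_tree_sample(
            cd.SimConfig(n_total=10, seed=4), n_trees=7, jitter_sd=0.05
        )
        assert len(sample) == 7
        assert frozenset(sample.trees[0].tip_labels) == frozenset(
            sim.chronogram.tip_labels
        )


class TestRangeEvolution:
    def test_zero_rates_inherit_root_range(self, yule_tree):
        cfg = cd.AreaSimConfig(root_range={"E"}, dispersal_rate=0.0,
                               extinction_rate=0.0, seed=0)
        rsim = cd.simulate_ranges(yule_tree.chronogram, cfg)
        assert all(r == frozenset("E") for r in rsim.tip_ranges.values())
        assert all(r == frozenset("E") for r in rsim.node_ranges.values())

    def test_loss_protection_keeps_last_area(self, yule_tree):
        cfg = cd.AreaSimConfig(root_range={"E"}, dispersal_rate=0.0,
                               extinction_rate=50.0, seed=1)
        rsim = cd.simulate_ranges(yule_tree.chronogram, cfg)
        assert all(r == frozenset("E") for r in rsim.tip_ranges.values())

    def test_range_size_capped(self, yule_tree):
        cfg = cd.AreaSimConfig(root_range={"A"}, dispersal_rate=20.0,
                               extinction_rate=0.0, max_range_size=2, seed=2)
        rsim = cd.simulate_ranges(yule_tree.chronogram, cfg)
        assert all(1 <= len(r) <= 2 for r in rsim.tip_ranges.values())

    def test_every_internal_node_recorded(self, yule_tree):
        cfg = cd.AreaSimConfig(seed=3)
        rsim = cd.simulate_ranges(yule_tree.chronogram, cfg)
        n = yule_tree.chronogram.n_tips
        assert len(rsim.node_ranges) == n - 1
        assert rsim.node_ranges[frozenset(yule_tree.chronogram.tip_labels)] == (
            rsim.root_range
        )

    def test_determinism(self, yule_tree):
        cfg = cd.AreaSimConfig(seed=12)
        a = cd.simulate_ranges(yule_tree.chronogram, cfg)
        b = cd.simulate_ranges(yule_tree.chronogram, cfg)
        assert a.tip_ranges == b.tip_ranges
        assert a.node_ranges == b.node_ranges
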