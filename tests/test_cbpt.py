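"""Cluster-based permutation test: statistics, clustering, significance."""

import numpy as np
import pytest

import popgrasp as pg
from popgrasp.cbpt import (
    Cluster,
    cbpt_test,
    cluster_threshold,
    extract_clusters,
    factor_tuning,
    permutation_null,
    pointwise_tstat,
    preferred_levels,
    run_population_cbpt,
    task_related,
    tuning_fraction,
)


class TestPointwiseT:
    def test_identical_groups_give_zero(self):
        x = np.random.default_rng(0).normal(size=(5, 20))
        assert np.allclose(pointwise_tstat(x, x), 0.0)

    def test_closed_form_toy_values(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[4.0], [5.0], [6.0]])
        # pooled-variance t for {1,2,3} vs {4,5,6}
        assert pointwise_tstat(a, b)[0] == pytest.approx(-3.674, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(4, 10)), rng.normal(size=(6, 10))
        assert np.allclose(pointwise_tstat(a, b), -pointwise_tstat(b, a))

    def test_zero_variance_defined_as_zero(self):
        a = np.ones((3, 4))
        b = np.ones((3, 4))
        assert np.allclose(pointwise_tstat(a, b), 0.0)


class TestClusters:
    def test_subthreshold_series_gives_no_clusters(self):
        t = np.full(50, 0.5)
        assert extract_clusters(t, threshold=2.0) == []

    def test_uniform_run_mass_is_count_times_value(self):
        t = np.zeros(30)
        t[10:15] = 3.0
        (c,) = extract_clusters(t, threshold=2.0)
        assert (c.start, c.stop) == (10, 15)
        assert c.mass == pytest.approx(5 * 3.0)
        assert c.sign == 1

    def test_sign_flip_splits_cluster(self):
        t = np.array([0.0, 3.0, 3.0, -3.0, -3.0, 0.0])
        clusters = extract_clusters(t, threshold=2.0)
        assert len(clusters) == 2
        assert clusters[0].sign == 1 and clusters[1].sign == -1
        assert clusters[0].mass == pytest.approx(6.0)

    def test_clusters_do_not_cross_segment_boundaries(self):
        t = np.full(10, 3.0)
        clusters = extract_clusters(t, threshold=2.0, segments=[(0, 5), (5, 10)])
        assert len(clusters) == 2
        assert [c.stop - c.start for c in clusters] == [5, 5]


class TestPermutationNull:
    def test_returns_requested_number_of_partitions(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(5, 30)), rng.normal(size=(5, 30))
        null = permutation_null(a, b, n_perm=1000, rng=np.random.default_rng(0))
        assert null.shape == (1000,)

    def test_constant_trials_give_all_zero_null(self):
        a = np.ones((4, 10))
        null = permutation_null(a, a, n_perm=50, rng=np.random.default_rng(0))
        assert np.array_equal(null, np.zeros(50))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(np.ones((1, 5)), np.ones((2, 5)), n_perm=10)


class TestCbpt:
    def test_identical_groups_never_significant(self):
        x = np.random.default_rng(3).normal(size=(6, 40))
        res = cbpt_test(x, x, seed=0)
        assert not res.significant

    def test_planted_step_detected_reliably(self):
        """A 200 ms, 10 Hz step with 10 trials per side is found."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(20.0, 7.0, size=(10, 100))
            b = rng.normal(20.0, 7.0, size=(10, 100))
            b[:, 40:60] += 10.0  # 20 samples at 10 ms = 200 ms
            res = cbpt_test(a, b, n_perm=500, seed=seed)
            sig = res.significant_clusters
            hits += any(c.start < 60 and c.stop > 40 for c in sig)
        assert hits >= 9

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(8, 50)), rng.normal(size=(8, 50))
        r1 = cbpt_test(a, b, n_perm=200, seed=7)
        r2 = cbpt_test(a, b, n_perm=200, seed=7)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_cluster_invariants(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, size=(10, 80))
        b = rng.normal(1.0, 1.0, size=(10, 80))
        res = cbpt_test(a, b, n_perm=200, seed=1)
        for c in res.clusters:
            assert c.mass > 0
            assert c.stop > c.start
        for c in res.significant_clusters:
            assert c.p_value < res.corrected_level


class TestPreferredLevels:
    def test_planted_orientation_preference(self):
        labels = np.repeat([-50, -25, 0, 25, 50], 8)
        sel = np.where(labels == 25, 30.0, 10.0) + np.random.default_rng(0).normal(
            0, 0.1, len(labels)
        )
        pref = preferred_levels(sel, labels, "orientation")
        assert pref.preferred == 25
        assert pref.non_preferred != 25
        assert not pref.tie

    def test_flat_unit_falls_back_to_tie_rule(self):
        labels = np.repeat(["power", "precision"], 6)
        pref = preferred_levels(np.zeros(12), labels, "grip")
        assert pref.tie
        assert pref.preferred == "power"  # lowest level index
        assert pref.non_preferred == "precision"

    def test_two_level_factor_uses_higher_mean(self):
        labels = np.repeat(["power", "precision"], 6)
        sel = np.where(labels == "precision", 5.0, 1.0)
        pref = preferred_levels(sel, labels, "grip")
        assert pref.preferred == "precision"


class TestFactorTuning:
    def test_planted_grip_only_flags_grip(self, grip_dataset):
        _, ds = grip_dataset
        res = run_population_cbpt(ds, n_perm=500, seed=3)
        for unit_res in res:
            assert unit_res["grip"].significant
            assert not unit_res["hand"].significant
            assert not unit_res["orientation"].significant
            assert task_related(unit_res)

    def test_tuning_fraction_curves(self, grip_dataset):
        _, ds = grip_dataset
        res = run_population_cbpt(ds, n_perm=300, seed=5)
        n_time = sum(len(a.time_grid()) for a in pg.default_alignments())
        frac_grip = tuning_fraction(res, "grip", n_time)
        frac_hand = tuning_fraction(res, "hand", n_time)
        assert frac_grip.max() == 100.0  # all units grip tuned somewhere
        assert frac_hand.max() <= 20.0

    def test_contra_ipsi_subset_drops_hand_factor(self, grip_dataset):
        _, ds = grip_dataset
        res = run_population_cbpt(
            ds, n_perm=100, seed=1, trial_subset="contra",
            factors=("hand", "grip", "orientation"),
        )
        assert set(res[0]) == {"grip", "orientation"}

    def test_orientation_requires_selection_stat(self):
        x = np.random.default_rng(0).normal(size=(40, 30))
        labels = np.repeat([-50, -25, 0, 25, 50], 8)
        with pytest.raises(ValueError, match="selection_stat"):
            factor_tuning(x, labels, "orientation")


def test_threshold_is_two_sided_critical_value():
    from scipy import stats

    assert cluster_threshold(0.05, 18) == pytest.approx(stats.t.ppf(0.975, 18))
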