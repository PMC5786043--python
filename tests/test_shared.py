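"""Shared-component selection, back-projection and threshold re-tuning."""

import numpy as np
import pytest

import popgrasp as pg
from popgrasp.dpca import DemixedPCA
from popgrasp.shared import (
    backproject,
    component_correlation,
    factor_level_range,
    select_shared,
    threshold_tuning,
)
from popgrasp.synth import condition_pattern


def _planted_pair(seed=0, n_units=20, t=30, noise=0.01, extra_ds0=None):
    """Two datasets sharing three latent components; optional ds0-only extra.

    Returns (X list, per-dataset fits, pooled fit).
    """
    rng = np.random.default_rng(seed)
    tags = ["time", "hand", "grip"]
    amps = [4.0, 3.0, 2.0]
    profs = [np.sin(np.linspace(0, (k + 1) * np.pi, t)) for k in range(3)]
    Xs = []
    for d in range(2):
        X = np.zeros((n_units, 20, t))
        for k, tag in enumerate(tags):
            load = rng.normal(size=n_units)
            pat = condition_pattern(tag).reshape(-1)
            X += amps[k] * np.einsum("u,c,t->uct", load, pat, profs[k])
        if d == 0 and extra_ds0 is not None:
            X += extra_ds0
        X += rng.normal(0, noise, size=X.shape)
        Xs.append(X)
    per = [DemixedPCA(X).fit(n_components=6, reg=1e-9) for X in Xs]
    pooled = DemixedPCA(np.concatenate(Xs, axis=0)).fit(n_components=6, reg=1e-9)
    return Xs, per, pooled


class TestComponentCorrelation:
    def test_self_correlation_is_one(self):
        v = np.random.default_rng(0).normal(size=100)
        assert component_correlation(v, v) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        v = np.random.default_rng(1).normal(size=100)
        assert component_correlation(v, -v) == pytest.approx(-1.0)

    def test_independent_noise_correlates_weakly(self):
        rng = np.random.default_rng(2)
        hits = sum(
            abs(component_correlation(rng.normal(size=2000), rng.normal(size=2000)))
            < 0.1
            for _ in range(50)
        )
        assert hits >= 49

    def test_zero_variance_flagged_as_zero(self):
        with pytest.warns(UserWarning):
            r = component_correlation(np.ones(10), np.arange(10.0))
        assert r == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            component_correlation(np.ones(5), np.ones(6))


class TestSelectShared:
    def test_identically_planted_components_all_retained(self):
        _, per, pooled = _planted_pair(seed=3)
        sel = select_shared(pooled, per, threshold=0.6)
        strong = np.flatnonzero(pooled.explained_var > 0.05)
        assert np.isin(strong, sel.retained).all()

    def test_impossible_threshold_discards_everything(self):
        _, per, pooled = _planted_pair(seed=4, noise=0.1)
        sel = select_shared(pooled, per, threshold=1.0)
        assert len(sel.retained) == 0
        assert len(sel.discarded) == pooled.n_components

    def test_retained_discarded_partition(self):
        _, per, pooled = _planted_pair(seed=5)
        sel = select_shared(pooled, per, threshold=0.6)
        both = np.sort(np.concatenate([sel.retained, sel.discarded]))
        assert np.array_equal(both, np.arange(pooled.n_components))
        assert np.all((sel.correlations >= -1) & (sel.correlations <= 1))

    def test_single_dataset_rejected(self):
        _, per, pooled = _planted_pair(seed=6)
        with pytest.raises(ValueError):
            select_shared(pooled, per[:1])

    def test_selection_idempotent_at_high_snr(self):
        Xs, per, pooled = _planted_pair(seed=7, noise=1e-4)
        sel = select_shared(pooled, per, threshold=0.6)
        recons = [backproject(sel, d, Xs[d].reshape(20, -1)) for d in range(2)]
        per2 = [DemixedPCA(r.reshape(20, 2, 2, 5, -1)).fit(6, reg=1e-9)
                for r in recons]
        pooled2 = DemixedPCA(
            np.concatenate(recons, axis=0).reshape(40, 2, 2, 5, -1)
        ).fit(6, reg=1e-9)
        sel2 = select_shared(pooled2, per2, threshold=0.6)
        # the strong shared components stay retained on reconstructed data
        strong = np.flatnonzero(pooled2.explained_var > 0.05)
        assert np.isin(strong, sel2.retained).all()


class TestBackproject:
    def test_empty_retained_set_gives_zero_and_warns(self):
        Xs, per, pooled = _planted_pair(seed=8, noise=0.1)
        sel = select_shared(pooled, per, threshold=1.0)
        with pytest.warns(UserWarning):
            recon = backproject(sel, 0, Xs[0].reshape(20, -1))
        assert np.array_equal(recon, np.zeros_like(recon))

    def test_retain_all_approximates_centered_data(self):
        Xs, per, pooled = _planted_pair(seed=9, noise=1e-5)
        sel = select_shared(pooled, per, threshold=0.0)
        X0 = Xs[0].reshape(20, -1)
        Xc = X0 - X0.mean(axis=1, keepdims=True)
        recon = backproject(sel, 0, X0)
        err = np.linalg.norm(recon - Xc) / np.linalg.norm(Xc)
        assert err < 1e-3  # only negligible discarded variance at high SNR

    def test_artifact_contribution_scores_point_at_source_dataset(self):
        rng = np.random.default_rng(10)
        t = 30
        art_prof = np.zeros(t)
        art_prof[5:12] = np.hanning(7)
        extra = 5.0 * np.einsum(
            "u,c,t->uct",
            rng.normal(size=20),
            condition_pattern("hand").reshape(-1),
            art_prof,
        )
        _, per, pooled = _planted_pair(seed=10, extra_ds0=extra)
        sel = select_shared(pooled, per, threshold=0.6)
        assert len(sel.discarded) > 0
        # every discarded component is driven by dataset 0 (the artifact host)
        top_discarded = sel.discarded[
            np.argmax(pooled.explained_var[sel.discarded])
        ]
        contrib = sel.contribution[top_discarded]
        assert contrib[0] > contrib[1]


class TestThresholdTuning:
    def test_zero_reconstruction_is_never_tuned(self):
        recon = np.zeros((5, 20 * 10))
        baseline = np.zeros(10, dtype=bool)
        baseline[:3] = True
        tuned, thr = threshold_tuning(recon, baseline, "hand", 0.05)
        assert not tuned.any()

    def test_planted_hand_population_exceeds_baseline(self):
        rng = np.random.default_rng(11)
        t = 20
        prof = np.r_[np.zeros(8), np.ones(12)]  # silent baseline, active late
        X = 5.0 * np.einsum(
            "u,c,t->uct",
            rng.normal(size=10),
            condition_pattern("hand").reshape(-1),
            prof,
        ) + rng.normal(0, 0.1, size=(10, 20, t))
        recon = X.reshape(10, -1)
        baseline = np.zeros(t, dtype=bool)
        baseline[:8] = True
        tuned, _ = threshold_tuning(recon, baseline, "hand", 0.05)
        tuned5 = tuned.reshape(10, t)
        assert tuned5[:, 8:].mean() > 0.9
        assert tuned5[:, :8].mean() < 0.15

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            threshold_tuning(np.zeros((2, 200)), np.zeros(10, dtype=bool))

    def test_level_range_matches_hand_difference(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(3, 2, 2, 5, 7))
        rng_range = factor_level_range(X.reshape(3, -1), "hand")
        manual = np.abs(X.mean(axis=(2, 3))[:, 0] - X.mean(axis=(2, 3))[:, 1])
        assert np.allclose(rng_range, manual)
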