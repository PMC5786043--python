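"""dPCA tests: marginalization algebra, PCA limit, regularization, CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import popgrasp as pg
from popgrasp.dpca import (
    DemixedPCA,
    MARGINALIZATION_TAGS,
    cross_validate_lambda,
    marginalize,
    pca_cumulative,
    variance_summary,
)
from popgrasp.synth import condition_pattern


def _random_tensor(seed, n_units=6, t=15):
    return np.random.default_rng(seed).normal(size=(n_units, 2, 2, 5, t))


class TestMarginalize:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_conservation_to_machine_precision(self, seed):
        X5 = _random_tensor(seed)
        m = marginalize(X5)
        Xc = X5 - X5.mean(axis=(1, 2, 3, 4), keepdims=True)
        total = sum(m.values())
        assert np.max(np.abs(total - Xc)) <= 1e-10 * max(1.0, np.abs(Xc).max())

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_orthogonality_on_balanced_grid(self, seed):
        m = marginalize(_random_tensor(seed))
        tags = list(m)
        scale = max(np.sum(v * v) for v in m.values())
        for i, a in enumerate(tags):
            for b in tags[i + 1:]:
                assert abs(np.sum(m[a] * m[b])) < 1e-9 * scale

    def test_constant_data_marginalizes_to_zero(self):
        X5 = np.full((3, 2, 2, 5, 8), 7.0)
        for v in marginalize(X5).values():
            assert np.allclose(v, 0.0)

    def test_pure_planted_grip_lands_in_grip_marginalization(self):
        rng = np.random.default_rng(0)
        load = rng.normal(size=4)
        prof = rng.normal(size=12)
        pat = condition_pattern("grip").reshape(-1)
        X = np.einsum("u,c,t->uct", load, pat, prof).reshape(4, 2, 2, 5, 12)
        m = marginalize(X)
        Xc = X - X.mean(axis=(1, 2, 3, 4), keepdims=True)
        assert np.allclose(m["grip"], Xc, atol=1e-10)
        for tag, v in m.items():
            if tag != "grip":
                assert np.max(np.abs(v)) < 1e-10


class TestFit:
    def test_pca_limit_matches_ordinary_pca(self):
        X5 = _random_tensor(1, n_units=8, t=20)
        res = DemixedPCA(X5, marginalizations=["full"]).fit(n_components=6, reg=0.0)
        pca = pca_cumulative(X5, 6)
        assert np.max(np.abs(res.cumulative_var - pca)) <= 1e-8

    def test_noiseless_planted_components_recovered(self):
        rng = np.random.default_rng(2)
        t = 30
        loads = np.linalg.qr(rng.normal(size=(10, 3)))[0].T  # orthogonal loadings
        profs = rng.normal(size=(3, t))
        pats = [condition_pattern(tag).reshape(-1)
                for tag in ("time", "hand", "grip")]
        X = sum(
            np.einsum("u,c,t->uct", loads[k], pats[k], profs[k])
            for k in range(3)
        ).reshape(10, 2, 2, 5, t)
        res = DemixedPCA(X).fit(n_components=3, reg=0.0)
        assert sorted(res.component_tags) == ["grip", "hand", "time"]
        assert res.cumulative_var[-1] > 1 - 1e-8

    def test_large_lambda_shrinks_components(self):
        X5 = _random_tensor(3)
        model = DemixedPCA(X5)
        small = model.fit(n_components=3, reg=1e-8)
        big = model.fit(n_components=3, reg=1e3)
        assert big.cumulative_var[-1] < 1e-3
        assert small.cumulative_var[-1] > big.cumulative_var[-1]

    def test_decoder_encoder_consistency_on_retained_subspace(self):
        X5 = _random_tensor(4, n_units=8)
        res = DemixedPCA(X5, marginalizations=["full"]).fit(n_components=5, reg=0.0)
        DF = res.decoder @ res.encoder
        assert np.allclose(DF, np.eye(5), atol=1e-8)

    def test_invalid_arguments_rejected(self):
        X5 = _random_tensor(5)
        with pytest.raises(ValueError):
            DemixedPCA(X5).fit(reg=-1.0)
        with pytest.raises(ValueError):
            DemixedPCA(X5).fit(n_components=100)
        with pytest.raises(ValueError):
            DemixedPCA(X5, marginalizations=["bogus"])

    def test_variance_shares_sum_to_one(self):
        X5 = _random_tensor(6)
        res = DemixedPCA(X5).fit(n_components=3, reg=1e-6)
        assert sum(res.marg_var_share.values()) == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in res.marg_var_share.values())


class TestVarianceSummary:
    def test_rank_one_data_fully_explained_by_first_component(self):
        rng = np.random.default_rng(7)
        X = np.outer(rng.normal(size=5), rng.normal(size=200))
        res = DemixedPCA(X, marginalizations=["full"]).fit(n_components=2, reg=0.0)
        assert res.explained_var[0] == pytest.approx(1.0, abs=1e-10)

    def test_dpca_cumulative_never_exceeds_pca(self):
        X5 = _random_tensor(8, n_units=10)
        res = DemixedPCA(X5).fit(n_components=8, reg=1e-7)
        df = variance_summary(res, X5)
        assert (df["cumulative_pct"] <= df["pca_cumulative_pct"] + 1e-9).all()

    def test_planted_variance_shares_recovered(self):
        rng = np.random.default_rng(9)
        t = 40
        amps = {"time": np.sqrt(50.0), "hand": np.sqrt(30.0), "grip": np.sqrt(20.0)}
        loads = np.linalg.qr(rng.normal(size=(12, 3)))[0].T

        def _unit(v):
            return v / np.linalg.norm(v)

        X = sum(
            amp * np.einsum(
                "u,c,t->uct",
                loads[k],
                _unit(condition_pattern(tag).reshape(-1)),
                _unit(rng.normal(size=t)),
            )
            for k, (tag, amp) in enumerate(amps.items())
        )
        X += rng.normal(0, 0.05, size=X.shape)  # low noise
        res = DemixedPCA(X.reshape(12, 2, 2, 5, t)).fit(n_components=3, reg=1e-8)
        shares = res.marg_var_share
        total = shares["time"] + shares["hand"] + shares["grip"]
        ratios = np.array([shares["time"], shares["hand"], shares["grip"]]) / total
        # planted 50/30/20 split, within 2% absolute
        assert np.allclose(ratios, [0.5, 0.3, 0.2], atol=0.02)


class TestCrossValidation:
    def test_noiseless_data_prefers_smallest_lambda(self, grip_rates):
        # effectively noiseless: use the planted tensor itself as trials
        avg = grip_rates.average_conditions()
        vals = np.repeat(avg.values, 2, axis=1)
        fake = pg.RateTensor(
            values=vals,
            alignments=avg.alignments,
            unit_ids=avg.unit_ids,
            mode="single_trial",
            trial_conditions=np.repeat(np.arange(pg.N_CONDITIONS), 2),
        )
        lam, table = cross_validate_lambda(
            fake, [1e-8, 1e-4, 1e-1], n_components=4, n_reps=1, seed=0
        )
        assert lam == 1e-8
        assert (np.diff(table["cv_error"]) >= 0).all()

    def test_noisy_data_prefers_positive_lambda(self, grip_rates):
        lam, _ = cross_validate_lambda(
            grip_rates, [0.0, 3e-6, 3e-3], n_components=4, n_reps=2, seed=1
        )
        assert lam > 0.0

    def test_empty_grid_rejected(self, grip_rates):
        with pytest.raises(ValueError):
            cross_validate_lambda(grip_rates, [])
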