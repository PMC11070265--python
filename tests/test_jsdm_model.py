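import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import pearsonr

from biodivmap.jsdm import (
    Hyperparameters,
    JSDMModel,
    LinearNet,
    auc,
    build_trend_surface,
    fit,
)


class TestTrendSurface:
    def test_degree_one_basis(self, rng):
        coords = rng.normal(size=(10, 2))
        ts = build_trend_surface(coords, degree=1)
        assert ts.basis_names == ["x", "y"]
        assert ts.transform(coords).shape == (10, 2)

    def test_degree_two_basis(self, rng):
        coords = rng.normal(size=(10, 2))
        ts = build_trend_surface(coords, degree=2)
        assert ts.basis_names == ["x", "y", "x^2", "x*y", "y^2"]
        assert ts.transform(coords).shape == (10, 5)

    def test_shift_invariance(self, rng):
        coords = rng.normal(size=(15, 2))
        a = build_trend_surface(coords, 2).transform(coords)
        shifted = coords + np.array([1234.5, -987.0])
        b = build_trend_surface(shifted, 2).transform(shifted)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_location_raises(self):
        coords = np.tile([3.0, 4.0], (5, 1))
        with pytest.raises(ValueError):
            build_trend_surface(coords)


class TestHyperparameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            Hyperparameters(env_penalty=-1)
        with pytest.raises(ValueError):
            Hyperparameters(env_mix=1.5)
        with pytest.raises(ValueError):
            Hyperparameters(mc_draws=0)

    def test_dict_roundtrip(self):
        h = Hyperparameters(latent_rank=3, hidden=(25, 25), lr=0.02)
        assert Hyperparameters.from_dict(h.to_dict()) == h


def _toy_data(rng, n=150, p=3, S=4, coef_scale=1.5):
    X = rng.normal(size=(n, p))
    coords = rng.uniform(0, 1000, size=(n, 2))
    W = np.zeros((p, S))
    for j in range(S):
        W[j % p, j] = coef_scale * (1 if j % 2 == 0 else -1)
    eta = X @ W
    Y = (eta + rng.normal(size=(n, S)) > 0).astype(np.int8)
    return X, coords, Y, W


class TestFit:
    def test_deterministic(self, rng):
        X, coords, Y, _ = _toy_data(rng)
        hyper = Hyperparameters(latent_rank=1, epochs=60, mc_draws=20)
        m1 = fit(Y, X, coords, hyper, seed=3)
        m2 = fit(Y, X, coords, hyper, seed=3)
        np.testing.assert_array_equal(m1.net.W, m2.net.W)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        np.testing.assert_array_equal(m1.trend_coef, m2.trend_coef)

    def test_extreme_penalty_shrinks_to_prevalence(self, rng):
        X, coords, Y, _ = _toy_data(rng, n=300)
        hyper = Hyperparameters(
            env_penalty=1e3, trend_penalty=1e3, loading_penalty=1e3,
            latent_rank=0, epochs=800, lr=0.05,
        )
        model = fit(Y, X, coords, hyper, seed=1)
        assert np.abs(model.net.W).max() < 1e-3
        prob = model.predict_prob(X, coords)
        prevalence = Y.mean(axis=0)
        assert np.all(np.abs(prob - prevalence) < 0.05)

    def test_recovery_correlation(self, recovery_case):
        land = recovery_case["landscape"]
        truth = recovery_case["truth"].reshape(10, -1).T
        pred = recovery_case["model"].predict_prob(land.pixel_matrix(), land.pixel_coords())
        r, _ = pearsonr(truth.ravel(), pred.ravel())
        assert r > 0.8

    def test_rank0_linear_limit_matches_probit_oracle(self, rng):
        # with no latent factors and no penalty, fit = independent
        # penalized probit regressions; statsmodels Probit is the oracle
        import statsmodels.api as sm

        n, p, S = 400, 3, 3
        X, coords, Y, _ = _toy_data(rng, n=n, p=p, S=S, coef_scale=1.0)
        hyper = Hyperparameters(
            env_penalty=0.0, trend_penalty=1e3, loading_penalty=0.0,
            latent_rank=0, epochs=4000, lr=0.05,
        )
        model = fit(Y, X, coords, hyper, seed=0)
        Xs = model.standardize(X)
        for j in range(S):
            res = sm.Probit(Y[:, j], sm.add_constant(Xs)).fit(disp=0)
            np.testing.assert_allclose(model.net.W[:, j], res.params[1:], atol=0.03)
            np.testing.assert_allclose(model.net.b[j], res.params[0], atol=0.03)

    def test_penalty_monotonicity(self, rng):
        X, coords, Y, _ = _toy_data(rng, n=200)
        norms = []
        for pen in (1e-3, 1e-1, 10.0):
            hyper = Hyperparameters(
                env_penalty=pen, env_mix=0.0, trend_penalty=1.0,
                loading_penalty=1.0, latent_rank=0, epochs=1500, lr=0.05,
            )
            model = fit(Y, X, coords, hyper, seed=2)
            norms.append(np.linalg.norm(model.net.W))
        assert norms[0] >= norms[1] >= norms[2]

    def test_divergence_reports_epoch_and_hyper(self, rng):
        X, coords, Y, _ = _toy_data(rng, n=50)
        X = X * 1e150  # overflow to inf in standardization product
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            fit(Y, X, coords, Hyperparameters(epochs=5), seed=0)

    def test_single_species_raises(self, rng):
        X, coords, Y, _ = _toy_data(rng)
        with pytest.raises(ValueError):
            fit(Y[:, :1], X, coords, Hyperparameters(), seed=0)

    def test_training_log_recorded(self, rng):
        X, coords, Y, _ = _toy_data(rng)
        model = fit(Y, X, coords, Hyperparameters(epochs=30, latent_rank=0), seed=0)
        assert len(model.training_log) == 30
        assert model.training_log[0] > model.training_log[-1]


def _manual_model(W, b, loadings, covariate_names=None):
    p, S = W.shape
    ts = build_trend_surface(np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 2.0]]), degree=1)
    return JSDMModel(
        net=LinearNet(W, b),
        loadings=loadings,
        trend=ts,
        trend_coef=np.zeros((ts.n_basis, S)),
        hyper=Hyperparameters(latent_rank=loadings.shape[1]),
        covariate_names=covariate_names or [f"c{k}" for k in range(p)],
        species_ids=[f"sp{j}" for j in range(S)],
        x_mean=np.zeros(p),
        x_sd=np.ones(p),
    )


class TestPredict:
    def test_zero_eta_gives_half(self):
        model = _manual_model(np.zeros((2, 3)), np.zeros(3), np.zeros((3, 0)))
        prob = model.predict_prob(np.zeros((4, 2)), np.zeros((4, 2)) + [[0.5, 0.5]])
        np.testing.assert_allclose(prob, 0.5)

    def test_marginal_matches_latent_monte_carlo(self, rng):
        W = rng.normal(size=(2, 3))
        loadings = rng.normal(0, 0.8, size=(3, 2))
        model = _manual_model(W, np.array([0.2, -0.1, 0.4]), loadings)
        X = rng.normal(size=(6, 2))
        coords = rng.uniform(0, 2, size=(6, 2))
        prob = model.predict_prob(X, coords)
        eta = model.linear_predictor(X, coords)
        M = 10**5
        h = rng.standard_normal((M, 2))
        mc = np.stack(
            [ndtr(eta[:, j][None, :] + (h @ loadings[j])[:, None]).mean(axis=0) for j in range(3)],
            axis=1,
        )
        se = np.sqrt(mc * (1 - mc) / M)
        assert np.all(np.abs(prob - mc) < 4 * se + 1e-3)

    def test_duplicated_row_duplicates_output(self, rng):
        W = rng.normal(size=(2, 2))
        model = _manual_model(W, np.zeros(2), np.zeros((2, 0)))
        X = rng.normal(size=(3, 2))
        coords = rng.uniform(size=(3, 2))
        X2 = np.vstack([X, X[1]])
        coords2 = np.vstack([coords, coords[1]])
        prob = model.predict_prob(X2, coords2)
        np.testing.assert_array_equal(prob[1], prob[3])

    def test_schema_mismatch_lists_names(self):
        model = _manual_model(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 0)),
                              covariate_names=["elev", "slope"])
        with pytest.raises(ValueError, match="slope"):
            model.predict_prob(np.zeros((1, 2)), np.zeros((1, 2)),
                               covariate_names=["elev", "tri"])


class TestSerialization:
    def test_roundtrip_bit_identical_predictions(self, rng, tmp_path):
        X, coords, Y, _ = _toy_data(rng)
        hyper = Hyperparameters(latent_rank=2, hidden=(8,), epochs=40, mc_draws=10)
        model = fit(Y, X, coords, hyper, seed=4)
        path = tmp_path / "model.jsdm"
        model.save(path)
        loaded = JSDMModel.load(path)
        Xn = rng.normal(size=(20, 3))
        cn = rng.uniform(0, 1000, size=(20, 2))
        np.testing.assert_array_equal(
            model.predict_prob(Xn, cn), loaded.predict_prob(Xn, cn)
        )
        assert loaded.hyper == model.hyper
        assert loaded.species_ids == model.species_ids

    def test_archive_bytes_stable(self, rng, tmp_path):
        X, coords, Y, _ = _toy_data(rng, n=60)
        model = fit(Y, X, coords, Hyperparameters(epochs=10, latent_rank=0), seed=1)
        p1, p2 = tmp_path / "a.jsdm", tmp_path / "b.jsdm"
        model.save(p1)
        model.save(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestAUC:
    def test_perfect_separation_is_one(self):
        labels = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        assert auc(scores, labels) == 1.0

    def test_perfect_inversion_is_zero(self):
        labels = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert auc(scores, labels) == 0.0

    def test_constant_scores_give_half(self):
        assert auc(np.full(8, 0.3), np.array([1, 0, 1, 0, 1, 0, 1, 0])) == 0.5

    def test_single_class_is_nan(self):
        assert np.isnan(auc(np.array([0.1, 0.9]), np.array([1, 1])))

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = rng.normal(size=40).round(1)  # ties included
            labels = (rng.random(40) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )
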