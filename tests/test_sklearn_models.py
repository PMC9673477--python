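"""Penalized linear, SVR, and tree-ensemble models behind the contract."""

import numpy as np
import pytest

from gsbench.genotypes import generate_synthetic_genotypes
from gsbench.models import (ElasticNetModel, LassoModel, RandomForestModel,
                            SVRModel, XGBoostModel, fit_penalized_linear,
                            penalized_objective)
from gsbench.simulate import SimulationConfig, simulate


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(20)
    X = rng.normal(size=(40, 25))
    w = np.zeros(25)
    w[[2, 7, 11]] = [1.5, -2.0, 1.0]
    y = X @ w + 0.3 * rng.normal(size=40)
    return X, y


@pytest.fixture(scope="module")
def config_c_data():
    G = generate_synthetic_genotypes(350, 600, seed=44)
    cfg = SimulationConfig(name="Cmini", n_samples=350, n_causal=1,
                           causal_fractions=[0.3], heritability=0.95,
                           n_background=250)
    sp = simulate(cfg, G, seed=2)
    return G.values[sp.truth.sample_indices].astype(float), sp


class TestPenalizedLinear:
    def test_huge_alpha_zeroes_all_coefficients(self, toy):
        X, y = toy
        _, w, _, _ = fit_penalized_linear(X, y, alpha=1e6, l1_ratio=1.0)
        assert (w == 0).all()

    def test_objective_beats_random_search_oracle(self, toy):
        X, y = toy
        X, y = X[:10, :5], y[:10]
        alpha = 0.1
        _, w, w0, obj = fit_penalized_linear(X, y, alpha=alpha, l1_ratio=0.5)
        assert obj <= penalized_objective(X, y, np.zeros(5), float(y.mean()), alpha, 0.5)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            w_r = rng.normal(0, 1.5, size=5)
            assert obj <= penalized_objective(X, y, w_r, float(y.mean()), alpha, 0.5) + 1e-9

    def test_l1_ratio_one_equals_lasso(self, toy):
        X, y = toy
        _, w_en, _, _ = fit_penalized_linear(X, y, alpha=2.0, l1_ratio=1.0)
        lasso = LassoModel(alpha=2.0).fit(X, y)
        assert np.allclose(w_en, lasso.w_, atol=1e-8)

    def test_l1_ratio_zero_matches_ridge_closed_form(self, toy):
        X, y = toy
        alpha = 5.0
        _, w, _, _ = fit_penalized_linear(X, y, alpha=alpha, l1_ratio=0.0, tol=1e-10)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        # objective 1/2||r||^2 + alpha ||w||^2 has stationarity (X'X + 2a I) w = X'y
        w_oracle = np.linalg.solve(Xc.T @ Xc + 2 * alpha * np.eye(X.shape[1]), Xc.T @ yc)
        assert np.allclose(w, w_oracle, atol=1e-4)

    def test_causal_marker_gets_largest_coefficient(self, config_c_data):
        X, sp = config_c_data
        model = ElasticNetModel(alpha=1.0, l1_ratio=0.5).fit(X, sp.y)
        assert int(np.argmax(np.abs(model.w_))) == int(sp.truth.causal_indices[0])
        assert np.count_nonzero(model.importance()) == np.count_nonzero(model.w_)

    def test_invalid_hyperparameters(self, toy):
        X, y = toy
        with pytest.raises(ValueError):
            fit_penalized_linear(X, y, alpha=-1.0, l1_ratio=0.5)
        with pytest.raises(ValueError):
            fit_penalized_linear(X, y, alpha=1.0, l1_ratio=1.5)


class TestSVR:
    def test_tube_wider_than_response_gives_flat_predictions(self, toy):
        X, y = toy
        model = SVRModel(C=1.0, epsilon_frac=5.0, kernel="rbf").fit(X, y)
        preds = model.predict(X)
        # all residuals sit inside the tube: predictions hug a constant
        assert np.std(preds) < 0.05 * np.std(y)

    def test_fits_signal_with_narrow_tube(self, toy):
        X, y = toy
        model = SVRModel(C=10.0, epsilon_frac=0.05, kernel="linear").fit(X, y)
        assert np.corrcoef(model.predict(X), y)[0, 1] > 0.9

    def test_importance_unsupported(self, toy):
        from gsbench.models import UnsupportedImportanceError
        X, y = toy
        with pytest.raises(UnsupportedImportanceError):
            SVRModel().fit(X, y).importance()


class TestEnsembles:
    @pytest.mark.parametrize("cls", [RandomForestModel, XGBoostModel])
    def test_importances_normalized_and_deterministic(self, toy, cls):
        X, y = toy
        a = cls(seed=3, n_estimators=100).fit(X, y)
        b = cls(seed=3, n_estimators=100).fit(X, y)
        imp = a.importance()
        assert imp.shape == (25,)
        assert imp.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(a.predict(X), b.predict(X))

    @pytest.mark.parametrize("cls", [RandomForestModel, XGBoostModel])
    def test_causal_marker_among_top_features(self, config_c_data, cls):
        X, sp = config_c_data
        model = cls(seed=1, n_estimators=200).fit(X, sp.y)
        top10 = np.argsort(-model.importance())[:10]
        assert int(sp.truth.causal_indices[0]) in top10
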