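"""ELM closed-form training and its averaging ensemble."""

import numpy as np
import pytest
from scipy import linalg

from hemoppg import (
    ELMParams,
    EnsembleModel,
    load_model,
    member_seed,
    predict_eelm,
    predict_elm,
    save_model,
    train_eelm,
    train_elm,
)
from hemoppg.eelm import ACTIVATIONS


def _toy(n=60, d=5, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + noise * rng.normal(size=n)
    return X, y


class TestTrainElm:
    def test_interpolation_regime_is_exact(self):
        """With N <= K distinct inputs the pseudoinverse fit interpolates."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        model = train_elm(X, y, K=20, seed=0)
        resid = predict_elm(model, X) - y
        assert np.sqrt(np.mean(resid**2)) <= 1e-6

    def test_beta_matches_normal_equations_oracle(self):
        """On a well-conditioned tall H, beta equals inv(H'H) H' y."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        model = train_elm(X, y, K=3, seed=7)
        H = ACTIVATIONS["sigmoid"](X @ model.W.T + model.b)
        oracle = linalg.solve(H.T @ H, H.T @ y.reshape(-1, 1), assume_a="pos")
        np.testing.assert_allclose(model.beta, oracle, atol=1e-8)

    @pytest.mark.parametrize("shape", [(20, 20), (12, 20), (20, 12)])
    def test_pseudoinverse_contract_on_random_problems(self, shape):
        """beta is the least-squares solution on random problems up to 20x20."""
        n, K = shape
        rng = np.random.default_rng(n * 100 + K)
        X = rng.normal(size=(n, 6))
        y = rng.normal(size=n)
        model = train_elm(X, y, K=K, seed=3)
        H = ACTIVATIONS["sigmoid"](X @ model.W.T + model.b)
        oracle, *_ = np.linalg.lstsq(H, y.reshape(-1, 1), rcond=None)
        np.testing.assert_allclose(H @ model.beta, H @ oracle, atol=1e-8)

    def test_deterministic_for_fixed_seed(self):
        X, y = _toy()
        a = train_elm(X, y, K=10, seed=11)
        b = train_elm(X, y, K=10, seed=11)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.W, b.W)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_elm(np.empty((0, 3)), np.empty(0), K=5)


class TestPredictElm:
    def test_zero_beta_predicts_zero(self):
        model = ELMParams(W=np.ones((3, 2)), b=np.zeros(3),
                          beta=np.zeros((3, 1)))
        np.testing.assert_array_equal(
            predict_elm(model, np.random.default_rng(0).normal(size=(4, 2))),
            np.zeros(4),
        )

    def test_training_row_reproduced_in_interpolation_regime(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = train_elm(X, y, K=15, seed=0)
        assert predict_elm(model, X[4:5])[0] == pytest.approx(y[4], abs=1e-6)

    def test_row_order_invariance(self):
        X, y = _toy()
        model = train_elm(X, y, K=8, seed=0)
        perm = np.random.default_rng(5).permutation(len(X))
        np.testing.assert_allclose(predict_elm(model, X)[perm],
                                   predict_elm(model, X[perm]))


class TestEnsemble:
    def test_single_member_matches_elm(self):
        X, y = _toy()
        ens = train_eelm(X, y, K=8, P=1, seed=21)
        single = train_elm(X, y, K=8, seed=member_seed(21, 0))
        np.testing.assert_array_equal(predict_eelm(ens, X), predict_elm(single, X))

    def test_members_have_distinct_hidden_layers(self):
        X, y = _toy()
        ens = train_eelm(X, y, K=8, P=5, seed=0)
        for i in range(1, 5):
            assert not np.array_equal(ens.members[0].W, ens.members[i].W)

    def test_mean_aggregation(self):
        # K=1, W=0, b=0 => hidden output is g(0)=0.5; beta=2c makes output c.
        members = [
            ELMParams(W=np.zeros((1, 2)), b=np.zeros(1),
                      beta=np.array([[2.0 * c]]))
            for c in (10.0, 14.0, 18.0)
        ]
        ens = EnsembleModel(members=members)
        np.testing.assert_allclose(predict_eelm(ens, np.zeros((1, 2))), [14.0])

    def test_matches_mean_of_member_predictions(self):
        X, y = _toy()
        ens = train_eelm(X, y, K=8, P=4, seed=9)
        manual = np.mean([predict_elm(m, X) for m in ens.members], axis=0)
        np.testing.assert_array_equal(predict_eelm(ens, X), manual)

    def test_ensemble_cuts_initialisation_variance_tenfold(self):
        """Across 50 re-trainings, EELM(P=50) varies <= 1/10 as much as one ELM."""
        X, y = _toy(n=60)
        X_test = np.random.default_rng(99).normal(size=(10, 5))
        single, ensemble = [], []
        for s in range(50):
            single.append(predict_elm(train_elm(X, y, K=20, seed=1000 + s), X_test))
            ensemble.append(predict_eelm(
                train_eelm(X, y, K=20, P=50, seed=2000 + s), X_test))
        var_single = np.var(single, axis=0).mean()
        var_ens = np.var(ensemble, axis=0).mean()
        assert var_ens <= var_single / 10

    def test_save_load_roundtrip(self, tmp_path):
        X, y = _toy()
        ens = train_eelm(X, y, K=6, P=3, seed=2)
        ens.feature_mask = np.array([0, 2, 3, 1, 4])[:5]
        ens.feature_mean = X.mean(axis=0)
        ens.feature_scale = X.std(axis=0)
        path = tmp_path / "model.npz"
        save_model(ens, path)
        back = load_model(path)
        assert back.n_members == 3
        np.testing.assert_array_equal(back.feature_mask, ens.feature_mask)
        Xr = np.random.default_rng(0).normal(size=(4, 5))
        np.testing.assert_allclose(predict_eelm(back, Xr), predict_eelm(ens, Xr))
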