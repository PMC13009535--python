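"""Kernel ridge prediction: oracles, leakage audit, Haufe activations."""

import numpy as np
import pytest

from connvar import predict as pr


class TestDeconfound:
    def test_perfectly_confounded_feature_zeroed_on_train(self, rng):
        age = rng.uniform(20, 40, 20)
        features = (2 * age)[:, None]
        train = np.arange(12)
        resid, _ = pr.deconfound(features, age[:, None], train)
        np.testing.assert_allclose(resid[train], 0.0, atol=1e-9)

    def test_orthogonal_covariate_only_demeans(self, rng):
        n = 100
        cov = rng.standard_normal(n)
        cov -= cov.mean()  # centered, so orthogonality includes the intercept
        f = rng.standard_normal(n)
        f -= f @ cov / (cov @ cov) * cov
        resid, _ = pr.deconfound(f[:, None], cov[:, None], np.arange(n))
        np.testing.assert_allclose(resid[:, 0], f - f.mean(), atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        features = rng.standard_normal((6, 2))
        cov = rng.standard_normal((6, 2))
        train = np.array([0, 1, 2, 4])
        resid, beta = pr.deconfound(features, cov, train)
        x = np.column_stack([cov, np.ones(6)])
        oracle = np.linalg.inv(x[train].T @ x[train]) @ x[train].T @ features[train]
        np.testing.assert_allclose(beta, oracle, atol=1e-10)
        np.testing.assert_allclose(resid, features - x @ oracle, atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        cov = np.ones((10, 2))  # duplicate of the intercept
        with pytest.raises(ValueError):
            pr.deconfound(rng.standard_normal((10, 3)), cov, np.arange(10))


class TestKrr:
    def test_matches_explicit_inverse_oracle(self):
        k = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        y = np.array([1.0, -1.0, 0.5])
        k_test = np.array([[0.4, 0.1, 0.9]])
        lam = 0.7
        pred = pr.krr_fit_predict(k, y, k_test, lam)
        oracle = k_test @ np.linalg.inv(k + lam * np.eye(3)) @ y
        np.testing.assert_allclose(pred, oracle, atol=1e-12)

    def test_huge_lambda_shrinks_predictions_to_zero(self, rng):
        k = pr.correlation_kernel(rng.standard_normal((10, 30)))
        y = rng.standard_normal(10)
        pred = pr.krr_fit_predict(k, y, k, 1e9)
        assert np.abs(pred).max() < 1e-6

    def test_interpolates_duplicated_training_subject(self, rng):
        feats = rng.standard_normal((10, 40))
        k = pr.correlation_kernel(feats)
        y = rng.standard_normal(10)
        k_test = pr.correlation_kernel(feats[[3]], feats)
        pred = pr.krr_fit_predict(k, y, k_test, 1e-8)
        assert pred[0] == pytest.approx(y[3], abs=1e-3)

    def test_singular_system_suggests_regularization(self):
        k = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            pr.krr_fit_predict(k, np.arange(3.0), k, 0.0)

    def test_equals_primal_ridge_with_linear_kernel(self, rng):
        # dual KRR with K = X X^T equals closed-form primal ridge
        x = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        lam = 2.5
        k = x @ x.T
        x_test = rng.standard_normal((3, 4))
        dual = pr.krr_fit_predict(k, y, x_test @ x.T, lam)
        w = np.linalg.inv(x.T @ x + lam * np.eye(4)) @ x.T @ y
        np.testing.assert_allclose(dual, x_test @ w, atol=1e-10)


class TestNestedCv:
    def test_single_lambda_reduces_to_plain_kfold(self, rng):
        n = 30
        feats = rng.standard_normal((n, 50))
        y = rng.standard_normal(n)
        folds = np.arange(n) % 5
        res = pr.nested_cv(feats, y, None, folds, lambda_grid=[1.0], task="regression")
        k = pr.correlation_kernel(feats)
        for f, acc in zip(range(5), res.fold_accuracy):
            te = np.flatnonzero(folds == f)
            tr = np.flatnonzero(folds != f)
            pred = pr.krr_fit_predict(k[np.ix_(tr, tr)], y[tr], k[np.ix_(te, tr)], 1.0)
            assert acc == pytest.approx(np.corrcoef(y[te], pred)[0, 1])

    def test_single_class_fold_rejected(self, rng):
        feats = rng.standard_normal((10, 20))
        y = np.r_[np.ones(5), -np.ones(5)]
        folds = np.r_[np.zeros(5), np.ones(5)]  # each training fold one-class
        with pytest.raises(ValueError):
            pr.nested_cv(feats, y, None, folds, [1.0], task="classification")

    def test_no_test_fold_leakage_into_training_artifacts(self, rng):
        # poisoning the held-out rows must leave every training-side
        # artifact (chosen lambda, training predictions) bit-identical
        n = 40
        feats = rng.standard_normal((n, 60))
        cov = rng.standard_normal((n, 2))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        y[:3] = 1.0  # ensure both classes in each fold
        y[3:6] = -1.0
        folds = np.arange(n) % 4
        res = pr.nested_cv(feats, y, cov, folds, [0.1, 10.0], task="classification")
        poisoned = feats.copy()
        poisoned[folds == 0] += 1e4
        res_p = pr.nested_cv(poisoned, y, cov, folds, [0.1, 10.0], task="classification")
        # fold 0 is the test fold of the first outer iteration
        assert res.chosen_lambda[0] == res_p.chosen_lambda[0]
        np.testing.assert_allclose(
            res.train_artifacts[0][1], res_p.train_artifacts[0][1], atol=1e-8
        )


class TestPermutationNull:
    def _engine(self, rng, n=24):
        feats = rng.standard_normal((n, 30))
        y = np.resize([1.0, -1.0], n)
        folds = np.arange(n) % 3
        return pr.CVEngine(feats, None, folds), y

    def test_extreme_p_values(self, rng):
        engine, y = self._engine(rng)
        p_low, _ = pr.permutation_null([engine], y, true_accuracy=2.0,
                                       lambda_grid=[1.0], n_perm=20, seed=0)
        assert p_low == 0.0
        p_high, _ = pr.permutation_null([engine], y, true_accuracy=-2.0,
                                        lambda_grid=[1.0], n_perm=20, seed=0)
        assert p_high == 1.0

    def test_conservative_correction(self, rng):
        engine, y = self._engine(rng)
        p, _ = pr.permutation_null([engine], y, true_accuracy=2.0, lambda_grid=[1.0],
                                   n_perm=20, seed=0, conservative=True)
        assert p == pytest.approx(1 / 21)

    def test_pairwise_permutation_preserves_pairs(self, rng):
        engine, y = self._engine(rng)
        pairs = [(i, i + 1) for i in range(0, len(y), 2)]
        _, nulls = pr.permutation_null([engine], y, 0.5, [1.0], n_perm=5, seed=1,
                                       pairs=pairs)
        assert len(nulls) == 5


class TestHaufe:
    def test_toy_fc1_fc2_activation_pattern(self, rng):
        # FC1 = Y - noise, FC2 = noise: perfect decoder weights are (1, 1)
        # but the activation of the noise channel vanishes
        n = 20_000
        y = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        feats = np.column_stack([y - noise, noise])
        y_hat = feats.sum(axis=1)  # the optimal decoder's output, = y exactly
        w = pr.haufe_weights(feats, y_hat)
        assert abs(w[1]) < 0.03
        assert w[0] == pytest.approx(1.0, abs=0.05)

    def test_feature_independent_of_prediction_gets_zero_weight(self, rng):
        feats = rng.standard_normal((5000, 2))
        yhat = feats[:, 0] * 2
        w = pr.haufe_weights(feats, yhat)
        assert abs(w[1]) < 0.1

    def test_constant_predictions_warn_and_zero(self, rng):
        with pytest.warns(UserWarning):
            w = pr.haufe_weights(rng.standard_normal((10, 3)), np.ones(10))
        np.testing.assert_array_equal(w, 0.0)

    def test_whitened_linear_model_recovers_primal_weights(self, rng):
        # for whitened features and a linear decoder, activations are
        # proportional to the decoder weights
        n, p = 50_000, 4
        feats = rng.standard_normal((n, p))
        w_primal = np.array([1.0, -2.0, 0.5, 0.0])
        yhat = feats @ w_primal
        w = pr.haufe_weights(feats, yhat)
        np.testing.assert_allclose(w, w_primal, atol=0.05)


class TestAggregateWeights:
    def test_constant_matrix_gives_constant_blocks(self):
        n = 6
        w = np.full((n, n), 2.5)
        np.fill_diagonal(w, 0)
        labels = np.array([1, 1, 1, 2, 2, 2])
        net, reg = pr.aggregate_weights(w, labels)
        np.testing.assert_allclose(net, 2.5)
        np.testing.assert_allclose(reg, 2.5)

    def test_two_network_toy_matches_hand_enumeration(self):
        w = np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [1.0, 0.0, 4.0, 5.0],
                [2.0, 4.0, 0.0, 6.0],
                [3.0, 5.0, 6.0, 0.0],
            ]
        )
        labels = np.array([1, 1, 2, 2])
        net, reg = pr.aggregate_weights(w, labels)
        assert net[0, 0] == pytest.approx(1.0)  # edge (0,1)
        assert net[1, 1] == pytest.approx(6.0)  # edge (2,3)
        assert net[0, 1] == pytest.approx((2 + 3 + 4 + 5) / 4)
        np.testing.assert_allclose(reg, [6 / 3, 10 / 3, 12 / 3, 14 / 3])

    def test_relabeling_invariance(self, rng):
        n = 8
        w = rng.standard_normal((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        labels = np.array([1, 1, 2, 2, 1, 2, 1, 2])
        perm = rng.permutation(n)
        net1, _ = pr.aggregate_weights(w, labels)
        net2, _ = pr.aggregate_weights(w[np.ix_(perm, perm)], labels[perm])
        np.testing.assert_allclose(net1, net2, atol=1e-12)

    def test_empty_network_rejected(self):
        w = np.zeros((3, 3))
        with pytest.raises(ValueError):
            pr.aggregate_weights(w, np.array([1, 1, np.nan]))

    def test_vectorize_roundtrip(self, rng):
        m = rng.standard_normal((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        np.testing.assert_allclose(pr.devectorize_conn(pr.vectorize_conn(m), 7), m)
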