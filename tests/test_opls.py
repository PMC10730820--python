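"""Latent-variable core: NIPALS PCA, OPLS-DA, Q2, permutations, VIP."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from metabotype import (
    OPLSDA,
    OPLSDAResults,
    cross_validate_q2,
    fit_oplsda,
    model_quality,
    nipals_pca,
    permutation_test,
)


def random_two_class(rng, n_per=10, p=30, delta=0.0):
    X = rng.normal(size=(2 * n_per, p))
    X[n_per:, : max(1, p // 10)] += delta
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


def sklearn_pls1_oracle(X, y01, n_comp):
    """Independent PLS1 reference: unit-variance scaled regression on coded y."""
    pls = PLSRegression(n_components=n_comp, scale=True, tol=1e-12, max_iter=1000)
    pls.fit(X, y01.astype(float))
    return pls.predict(X).ravel()


class TestNipalsPca:
    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 4))
        scores, loadings, r2x = nipals_pca(X, n_comp=3)
        Xc = X - X.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(3):
            v = vt[a] * np.sign(vt[a][np.argmax(np.abs(vt[a]))])
            np.testing.assert_allclose(loadings[:, a], v, atol=1e-8)
            np.testing.assert_allclose(scores[:, a], Xc @ v, atol=1e-8)
            np.testing.assert_allclose(r2x[a], s[a] ** 2 / np.sum(s**2), atol=1e-10)

    def test_rank_one_matrix_single_component(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.array([0.5, -1.0, 2.0])
        X = np.outer(t, p)
        _, _, r2x = nipals_pca(X, n_comp=2)
        assert r2x[0] == pytest.approx(1.0)
        assert r2x[1] == pytest.approx(0.0, abs=1e-12)

    def test_scores_orthogonal_and_r2_nonincreasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 8))
        scores, loadings, r2x = nipals_pca(X, n_comp=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-7 * np.max(np.diag(gram))
        assert np.all(np.diff(r2x) <= 1e-12)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            nipals_pca(np.eye(3), n_comp=3)


class TestOplsdaFit:
    def test_zero_ortho_equals_pls1_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X, y = random_two_class(rng, n_per=10, p=30, delta=1.0)
            res = fit_oplsda(X, y, n_pred=1, n_ortho=0)
            oracle = sklearn_pls1_oracle(X, (y == "b").astype(float), n_comp=1)
            np.testing.assert_allclose(res.fitted_values, oracle, atol=1e-8)

    def test_zero_ortho_two_components_equals_pls1_oracle(self):
        rng = np.random.default_rng(3)
        X, y = random_two_class(rng, n_per=10, p=20, delta=0.8)
        res = fit_oplsda(X, y, n_pred=2, n_ortho=0)
        oracle = sklearn_pls1_oracle(X, (y == "b").astype(float), n_comp=2)
        np.testing.assert_allclose(res.fitted_values, oracle, atol=1e-8)

    def test_separated_clouds_high_r2y(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 15))
        X[10:, :] += 5.0
        res = fit_oplsda(X, ["a"] * 10 + ["b"] * 10)
        assert res.diagnostics.r2y_cum >= 0.9

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_oplsda(np.random.default_rng(5).normal(size=(8, 4)), ["a"] * 8)

    def test_weights_unit_norm_and_score_orthogonality(self):
        rng = np.random.default_rng(6)
        X, y = random_two_class(rng, delta=1.5)
        res = fit_oplsda(X, y, n_pred=1, n_ortho=2)
        for a in range(res.n_pred):
            assert np.linalg.norm(res.weights[:, a]) == pytest.approx(1.0)
        for a in range(res.n_ortho):
            assert np.linalg.norm(res.weights_ortho[:, a]) == pytest.approx(1.0)
            dot = abs(res.scores[:, 0] @ res.scores_ortho[:, a])
            scale = np.linalg.norm(res.scores[:, 0]) * np.linalg.norm(res.scores_ortho[:, a])
            assert dot < 1e-8 * scale

    def test_r2y_nondecreasing_in_n_pred(self):
        rng = np.random.default_rng(7)
        X, y = random_two_class(rng, delta=0.5)
        r2 = [fit_oplsda(X, y, n_pred=k, n_ortho=0).diagnostics.r2y_cum for k in (1, 2, 3)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_training_prediction_consistency(self):
        rng = np.random.default_rng(8)
        X, y = random_two_class(rng, delta=1.0)
        res = fit_oplsda(X, y, n_pred=1, n_ortho=1)
        y_hat, labels = res.predict(X)
        np.testing.assert_allclose(y_hat, res.fitted_values, atol=1e-10)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        X, y = random_two_class(rng, delta=1.0)
        res = fit_oplsda(X, y)
        perm = rng.permutation(len(X))
        y_hat, _ = res.predict(X)
        y_hat_perm, _ = res.predict(X[perm])
        np.testing.assert_allclose(y_hat_perm, y_hat[perm])

    def test_excess_orthogonal_components_rejected(self):
        rng = np.random.default_rng(10)
        X, y = random_two_class(rng, n_per=3, p=5, delta=1.0)
        with pytest.raises(ValueError, match="n_ortho"):
            fit_oplsda(X, y, n_ortho=5)


class TestPredictLinearForm:
    def test_hand_arithmetic(self):
        res = OPLSDAResults.__new__(OPLSDAResults)
        res.feature_names = ["f1", "f2"]
        res.classes_ = ("neg", "pos")
        res.x_mean = np.zeros(2)
        res.x_sd = np.ones(2)
        res.coef = np.array([2.0, -1.0])
        res.intercept = 0.0
        y_hat = res.decision_function(np.array([[1.0, 1.0]]))
        assert y_hat[0] == pytest.approx(1.0)
        _, labels = res.predict(np.array([[1.0, 1.0]]))
        assert labels[0] == "pos"

    def test_missing_feature_named_in_error(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        X, y = random_two_class(rng, n_per=5, p=4)
        res = fit_oplsda(X, y, feature_names=["a", "b", "c", "d"])
        with pytest.raises(KeyError, match="d"):
            res.predict(pd.DataFrame(np.ones((2, 3)), columns=["a", "b", "c"]))


class TestCrossValidation:
    def test_perfect_linear_signal(self):
        y = np.array(["a"] * 10 + ["b"] * 10)
        X = ((y == "b").astype(float) * 2 - 1).reshape(-1, 1)  # y exactly linear in x
        q2 = cross_validate_q2(X, (y == "b").astype(float), n_ortho=0, folds=5, seed=0)
        assert q2 >= 0.99

    def test_null_median_q2_nonpositive(self):
        rng = np.random.default_rng(13)
        q2s = []
        for seed in range(30):
            X = rng.normal(size=(20, 50))
            y = np.array([0.0] * 10 + [1.0] * 10)
            q2s.append(cross_validate_q2(X, y, folds=7, seed=seed))
        assert np.median(q2s) <= 0.0
        assert np.all(np.asarray(q2s) <= 1.0)

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(16, 12))
        y = np.array([0.0] * 8 + [1.0] * 8)
        q2 = cross_validate_q2(X, y, folds=4, seed=3)
        perm = rng.permutation(12)
        q2_perm = cross_validate_q2(X[:, perm], y, folds=4, seed=3)
        assert q2 == pytest.approx(q2_perm, abs=1e-10)


class TestPermutation:
    def test_strong_signal_minimal_pq2(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 10))
        X[10:, :3] += 4.0
        y = np.array([0.0] * 10 + [1.0] * 10)
        report = permutation_test(X, y, n_perm=49, seed=0)
        assert report.p_q2 == pytest.approx(1 / 50)

    def test_null_pq2_not_small(self):
        rng = np.random.default_rng(16)
        big = []
        for seed in range(10):
            X = rng.normal(size=(16, 20))
            y = np.array([0.0] * 8 + [1.0] * 8)
            report = permutation_test(X, y, n_perm=39, seed=seed)
            big.append(report.p_q2 > 0.05)
        assert np.mean(big) >= 0.8

    def test_pq2_lower_bound(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(12, 6))
        y = np.array([0.0] * 6 + [1.0] * 6)
        report = permutation_test(X, y, n_perm=9, seed=1)
        assert report.p_q2 >= 1 / 10
        assert report.p_q2 <= 1.0

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.eye(6), np.array([0, 0, 0, 1, 1, 1.0]), n_perm=0)


class TestVip:
    def test_equal_weights_all_unity(self):
        rng = np.random.default_rng(18)
        res = fit_oplsda(*random_two_class(rng, delta=1.0), n_pred=1, n_ortho=0)
        p = len(res.feature_names)
        res.weights = np.full((p, 1), 1 / np.sqrt(p))
        np.testing.assert_allclose(res.vip().to_numpy(), 1.0)

    def test_hand_example_two_features(self):
        res = fit_oplsda(
            *random_two_class(np.random.default_rng(19), p=2, delta=1.0),
            n_pred=1, n_ortho=0,
        )
        res.weights = np.array([[0.8], [0.6]])
        np.testing.assert_allclose(
            res.vip().to_numpy(), [0.8 * np.sqrt(2), 0.6 * np.sqrt(2)], atol=1e-12
        )

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(20)
        res = fit_oplsda(*random_two_class(rng, delta=1.0), n_pred=2, n_ortho=1)
        assert (res.vip() ** 2).mean() == pytest.approx(1.0, abs=1e-8)


class TestModelQuality:
    @pytest.mark.parametrize(
        "q2,verdict", [(0.572, "good"), (-0.029, "none"), (0.3, "some")]
    )
    def test_verdict_thresholds(self, q2, verdict):
        assert model_quality(q2).verdict == verdict

    def test_rejection_rule(self):
        assert model_quality(-0.029).rejected
        assert model_quality(0.572, pq2=0.02).rejected is False
        assert model_quality(0.572, pq2=0.05).rejected  # boundary: pQ2 >= 0.05
        with pytest.raises(ValueError):
            model_quality(1.2)


class TestSerialization:
    def test_round_trip_predicts_identically(self, tmp_path):
        rng = np.random.default_rng(21)
        X, y = random_two_class(rng, delta=1.0)
        res = fit_oplsda(X, y, n_pred=1, n_ortho=1)
        path = tmp_path / "model.json"
        res.to_json(path)
        portable = OPLSDAResults.from_json(path)
        X_new = rng.normal(size=(5, X.shape[1]))
        np.testing.assert_allclose(
            portable.predict(X_new)[0], res.predict(X_new)[0], atol=1e-12
        )
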