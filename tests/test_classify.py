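"""Hybrid classifiers: boosting arithmetic, reduction identities,
ARIMA parameter recovery and baseline behavior."""
import numpy as np
import pytest
from sklearn.svm import SVC

from bcghyper import classify
from bcghyper.containers import FeatureTable
from bcghyper.synth import SynthTableConfig, generate_feature_table


class TestMULDA:
    def test_regularized_spectrum_is_elementwise_max_with_mean(self):
        lam_star, lam_bar = classify.regularize_spectrum([4.0, 2.0, 0.1, 0.1])
        assert lam_bar == pytest.approx(1.55)
        np.testing.assert_allclose(lam_star, [4.0, 2.0, 1.55, 1.55])
        # larger eigenvalues unchanged, none below the mean
        assert np.min(lam_star) >= lam_bar - 1e-15

    def test_spherical_scatter_reduces_to_plain_lda(self):
        """When all within-class eigenvalues are equal, the regularization
        is a no-op and the discriminant direction equals closed-form LDA's
        Sw^-1 (mu1 - mu0)."""
        rng = np.random.default_rng(0)
        n = 200
        y = np.array([0] * 100 + [1] * 100)
        X = rng.standard_normal((n, 2))
        X[y == 1] += [2.0, 1.0]
        # force exactly spherical within-class scatter via whitening
        Xc = X.copy()
        for cls in (0, 1):
            block = Xc[y == cls] - Xc[y == cls].mean(axis=0)
            cov = block.T @ block / len(block)
            w = np.linalg.cholesky(np.linalg.inv(cov))
            Xc[y == cls] = block @ w + X[y == cls].mean(axis=0)
        model = classify.mulda_fit(Xc, y)
        np.testing.assert_allclose(
            model.regularized_eigenvalues, model.eigenvalues, rtol=1e-8
        )
        mu0 = Xc[y == 0].mean(axis=0)
        mu1 = Xc[y == 1].mean(axis=0)
        Sw = np.zeros((2, 2))
        for cls in (0, 1):
            b = Xc[y == cls] - Xc[y == cls].mean(axis=0)
            Sw += b.T @ b
        lda_dir = np.linalg.solve(Sw, mu1 - mu0)
        lda_dir /= np.linalg.norm(lda_dir)
        got = model.discriminants[:, 0] / np.linalg.norm(model.discriminants[:, 0])
        assert min(np.linalg.norm(got - lda_dir), np.linalg.norm(got + lda_dir)) < 1e-6

    def test_separated_gaussians_project_cleanly(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 100 + [1] * 100)
        X = rng.standard_normal((200, 2))
        X[y == 1] += 4.0
        clf = classify.MULDAKNN().fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            classify.mulda_fit(np.ones((2, 3)), np.array([0, 1]))


class TestAdaBoost:
    def test_alpha_arithmetic(self):
        assert classify.alpha_from_error(0.5) == pytest.approx(0.0, abs=1e-9)
        assert classify.alpha_from_error(0.1) == pytest.approx(
            0.5 * np.log(9), abs=1e-12
        )

    def test_weights_normalized_every_round(self, default_table):
        ens = classify.hybrid_adaboost_mulda(default_table, T=8, seed=0)
        for D in ens.sample_weights_history:
            assert D.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(D >= 0)

    def test_training_error_obeys_product_bound(self):
        for seed in range(3):
            t = generate_feature_table(
                SynthTableConfig(n_samples=120, d_informative=3, d_noise=5,
                                 effect_size=1.0, seed=seed)
            )
            ens = classify.hybrid_adaboost_rf(t, T=10, seed=seed)
            train_err = float((ens.predict(t.values) != t.labels).mean())
            assert train_err <= classify.boosting_error_bound(ens.errors) + 1e-12

    def test_single_round_equals_base_learner(self, default_table):
        """T=1 with uniform weights trains the base learner on the full
        sample, so ensemble predictions coincide with the plain model."""
        ens = classify.hybrid_adaboost_mulda(default_table, T=1, seed=4)
        base = classify.MULDAKNN().fit(default_table.values, default_table.labels)
        np.testing.assert_array_equal(
            ens.predict(default_table.values), base.predict(default_table.values)
        )

    def test_single_round_rf_equals_plain_forest(self, default_table):
        from sklearn.ensemble import RandomForestClassifier

        ens = classify.hybrid_adaboost_rf(default_table, T=1, n_trees=10,
                                          max_depth=3, seed=6)
        rf = RandomForestClassifier(n_estimators=10, max_depth=3,
                                    random_state=6).fit(
            default_table.values, default_table.labels
        )
        np.testing.assert_array_equal(
            ens.predict(default_table.values), rf.predict(default_table.values)
        )

    def test_boosting_reaches_perfect_training_fit(self, separable_table):
        ens = classify.hybrid_adaboost_mulda(separable_table, T=10, seed=0)
        assert (ens.predict(separable_table.values) == separable_table.labels).all()

    def test_degenerate_identical_rows_do_not_crash(self):
        t = FeatureTable(np.ones((20, 3)), ["a", "b", "c"],
                         np.array([0, 1] * 10))
        ens = classify.hybrid_adaboost_rf(t, T=3, seed=0)
        assert ens.rounds >= 1


class TestARIMA:
    def test_white_noise_yields_small_ar_coefficients(self):
        rng = np.random.default_rng(2)
        spec = classify.arima_features(rng.standard_normal(2000), orders=(2, 0, 0))
        assert np.all(np.abs(spec.ar_coefs) <= 0.1)

    def test_ar1_coefficient_recovery(self):
        """phi = 0.7 recovered within the sampling band [0.6, 0.8]; the
        independent Yule-Walker estimate agrees."""
        rng = np.random.default_rng(3)
        x = np.zeros(2000)
        for i in range(1, 2000):
            x[i] = 0.7 * x[i - 1] + rng.standard_normal()
        spec = classify.arima_features(x, orders=(1, 0, 0))
        assert 0.6 <= spec.ar_coefs[0] <= 0.8
        # Yule-Walker oracle: lag-1 autocorrelation
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert spec.ar_coefs[0] == pytest.approx(r1, abs=0.05)

    def test_differencing_removes_linear_trend(self):
        x = 3.0 * np.arange(100) + 2.0
        d1 = np.diff(x)
        np.testing.assert_allclose(d1, 3.0)

    def test_stationary_series_screened_to_no_differencing(self):
        rng = np.random.default_rng(4)
        spec = classify.arima_features(rng.standard_normal(1000), orders=(2, 1, 2))
        assert spec.stationary

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            classify.arima_features(np.arange(10.0), orders=(1, 1, 1))


class TestARIMAAdaBoost:
    def test_chance_round_gets_zero_connection_weight(self):
        # beta = eps/(1-eps) = 1 at eps = 0.5 so w = 0.5*log(1) = 0
        assert 0.5 * np.log(1.0 / (0.5 / 0.5)) == 0.0

    def test_perfect_round_gives_single_tree_ensemble(self):
        y = np.array([0] * 20 + [1] * 20)
        X = y[:, None].astype(float)  # one perfect splitter
        model = classify.arima_adaboost_fit(X, y, T=10, seed=0)
        assert len(model.trees) == 1
        np.testing.assert_array_equal(model.predict(X), y)

    def test_separable_table_classified_correctly(self, separable_table):
        model = classify.arima_adaboost_fit(
            separable_table.values, separable_table.labels, T=20, seed=0
        )
        acc = (model.predict(separable_table.values) == separable_table.labels).mean()
        assert acc >= 0.95


class TestTWHASVM:
    def test_time_weight_values(self):
        assert classify.time_weight(0, 0.37) == pytest.approx(1.0)
        assert classify.time_weight(1, 0.5) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_eta_out_of_range_rejected(self, default_table):
        with pytest.raises(ValueError):
            classify.tw_hasvm_fit(default_table, eta=0.7)

    def test_correct_prediction_leaves_weight_unchanged(self):
        # exp(alpha * 0) = 1 for any alpha
        assert np.exp(1.23 * 0) == 1.0

    def test_weighted_vote_prediction(self):
        class Fixed:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.full(len(X), self.label)

        model = classify.TWHASVMModel(eta=0.0, batch_index=1)
        model.svms = [Fixed(1), Fixed(0)]
        model.alphas = [2.0, 1.0]
        assert model.predict(np.zeros((3, 2)))[0] == 1
        model.alphas = [1.0, 1.0]  # tie: lower class index wins
        assert model.predict(np.zeros((3, 2)))[0] == 0

    def test_single_learner_prediction_equals_svm(self, default_table):
        model = classify.tw_hasvm_fit(default_table, eta=0.0, T=1, seed=0)
        svm = SVC(kernel="poly", degree=3, C=1.0, random_state=0).fit(
            default_table.values, default_table.labels
        )
        np.testing.assert_array_equal(
            model.predict(default_table.values), svm.predict(default_table.values)
        )

    def test_zero_eta_equals_plain_adaboost_of_svms(self):
        """TW(0) = 1 makes time-weighting a no-op: predictions must match a
        plain (un-time-weighted) AdaBoost of polynomial SVMs coded
        independently here, run side by side with shared seeds."""
        t = generate_feature_table(
            SynthTableConfig(n_samples=120, d_informative=2, d_noise=6,
                             effect_size=1.0, seed=8)
        )
        X, y = t.values, t.labels
        n = len(y)
        seed, T = 5, 8

        # independent plain boosted-SVM pipeline (no time weights)
        rng = np.random.default_rng(seed)
        w = np.full(n, 1.0 / n)
        svms, alphas = [], []
        for tt in range(T):
            w = w / w.sum()
            idx = np.arange(n) if np.ptp(w) < 1e-15 else rng.choice(n, n, p=w)
            svm = SVC(kernel="poly", degree=3, C=1.0, random_state=seed + tt)
            svm.fit(X[idx], y[idx])
            miss = svm.predict(X) != y
            e = float(np.sum(w * miss) / np.sum(w))
            if e >= 0.5:
                break
            e_c = max(e, 1e-10)
            a = 0.5 * np.log((1 - e_c) / e_c)
            svms.append(svm)
            alphas.append(a)
            w = w * np.exp(a * miss)
            if e <= 1e-10:
                break
        scores = np.zeros((n, 2))
        for svm, a in zip(svms, alphas):
            pred = svm.predict(X)
            for ci in (0, 1):
                scores[:, ci] += a * (pred == ci)
        oracle_pred = np.argmax(scores, axis=1)

        tw = classify.tw_hasvm_fit(t, eta=0.0, batch_index=1, T=T, seed=seed)
        np.testing.assert_array_equal(tw.predict(X), oracle_pred)

    def test_eta_irrelevant_for_single_batch(self):
        """With one data batch the time weight is a scalar that renormalizes
        away: any eta gives identical predictions."""
        t = generate_feature_table(
            SynthTableConfig(n_samples=100, d_informative=2, d_noise=4,
                             effect_size=1.0, seed=12)
        )
        a = classify.tw_hasvm_fit(t, eta=0.0, batch_index=1, T=5, seed=2)
        b = classify.tw_hasvm_fit(t, eta=0.5, batch_index=1, T=5, seed=2)
        np.testing.assert_array_equal(a.predict(t.values), b.predict(t.values))
        np.testing.assert_allclose(a.alphas, b.alphas, atol=1e-12)


class TestBaselines:
    def test_gaussian_nb_matches_analytic_bayes_accuracy(self):
        """Two unit-variance Gaussians at +-2: Bayes accuracy Phi(2) ~ 97.7%."""
        from scipy.stats import norm

        rng = np.random.default_rng(9)
        y = np.array([0] * 1000 + [1] * 1000)
        X = rng.standard_normal((2000, 1)) + np.where(y == 1, 2.0, -2.0)[:, None]
        nbc = classify.baseline_classifier("nbc").fit(X, y)
        acc = (nbc.predict(X) == y).mean()
        assert abs(acc - norm.cdf(2.0)) < 0.02

    def test_single_sample_table_raises_not_crashes(self):
        clf = classify.baseline_classifier("adaboost")
        with pytest.raises(ValueError):
            clf.fit(np.ones((1, 2)), np.array([0]))

    def test_fixed_seed_reproducible_predictions(self, default_table):
        a = classify.baseline_classifier("rf", seed=3).fit(
            default_table.values, default_table.labels
        )
        b = classify.baseline_classifier("rf", seed=3).fit(
            default_table.values, default_table.labels
        )
        np.testing.assert_array_equal(
            a.predict(default_table.values), b.predict(default_table.values)
        )

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            classify.baseline_classifier("mystery")
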