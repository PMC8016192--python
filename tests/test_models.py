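"""Classifier correctness against independent probabilistic oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import LinearConstraint, minimize
from scipy.special import logsumexp
from scipy.stats import norm

from allostate.featurize import FEATURE_COLUMNS
from allostate.models import (SVM_PRESETS, load_model, predict_nb,
                              save_model, search_hyperparameters, train_gnb,
                              train_knb, train_svm)
from allostate.synthetic import sample_feature_matrix

from conftest import labeled_frame, make_single_gaussian_mixtures


def nb_oracle_posterior(model, X):
    """Independent Bayes-rule computation: Gaussian densities times the
    prior, normalized, without reusing the model's likelihood code."""
    log_a = norm.logpdf(X, model.means[0],
                        np.sqrt(model.variances[0])).sum(axis=1) \
        + np.log(model.priors["A"])
    log_i = norm.logpdf(X, model.means[1],
                        np.sqrt(model.variances[1])).sum(axis=1) \
        + np.log(model.priors["I"])
    return np.exp(log_i - np.logaddexp(log_a, log_i))


def knb_oracle_posterior(model, X):
    """Independent KDE Bayes oracle from the stored training values."""
    logs = {}
    for ci, cls in enumerate(("A", "I")):
        total = np.log(model.priors[cls]) * np.ones(len(X))
        for j in range(X.shape[1]):
            v = model.train_values[cls][:, j]
            h = model.bandwidths[ci, j]
            dens = norm.pdf(X[:, j][:, None], v[None, :], h).mean(axis=1)
            total = total + np.log(dens)
        logs[cls] = total
    return np.exp(logs["I"] - np.logaddexp(logs["A"], logs["I"]))


def svm_qp_oracle(Z, y_signed, sigma, C):
    """Dense dual quadratic program of the soft-margin RBF SVM."""
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * sigma ** 2))
    Q = (y_signed[:, None] * y_signed[None, :]) * K
    n = len(y_signed)
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.full(n, C / 2), jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[LinearConstraint(y_signed[None, :], 0.0, 0.0)],
        method="SLSQP", options={"maxiter": 5000, "ftol": 1e-18})
    alpha = res.x
    free = (alpha > 1e-8) & (alpha < C - 1e-8)
    bias = float(np.mean(y_signed[free] - (alpha * y_signed) @ K[:, free]))
    return alpha, bias, K


class TestGNB:
    def test_hand_statistics_one_feature(self):
        X = np.tile([0.0, 2.0, 10.0, 12.0], (8, 1)).T
        df = labeled_frame(X, ["A", "A", "I", "I"])
        model = train_gnb(df)
        assert model.means[0, 0] == pytest.approx(1.0)
        assert model.means[1, 0] == pytest.approx(11.0)
        assert model.priors == {"A": 0.5, "I": 0.5}

    def test_balanced_set_gives_equal_priors(self, gaussian_mixtures):
        a = sample_feature_matrix(gaussian_mixtures, 200, "A", 1)
        i = sample_feature_matrix(gaussian_mixtures, 200, "I", 2)
        model = train_gnb(pd.concat([a, i], ignore_index=True))
        assert model.priors == {"A": 0.5, "I": 0.5}

    def test_posterior_matches_bayes_oracle(self, rng):
        X = rng.normal(0, 2, (300, 8))
        labels = rng.choice(["A", "I"], 300, p=[0.4, 0.6])
        X[labels == "I"] += 1.0
        df = labeled_frame(X, labels)
        model = train_gnb(df)
        pred = predict_nb(model, df)
        oracle = nb_oracle_posterior(model, X)
        np.testing.assert_allclose(pred["posterior_I"].to_numpy(), oracle,
                                   atol=1e-10)

    def test_tie_at_half_goes_to_A(self):
        # classes mirror each other in every feature: the origin is
        # exactly equidistant, posterior 1/2
        X = np.tile([-1.0, -3.0, 1.0, 3.0], (8, 1)).T
        df = labeled_frame(X, ["A", "A", "I", "I"])
        model = train_gnb(df)
        mid = labeled_frame(np.zeros((1, 8)), ["A"])
        pred = predict_nb(model, mid)
        assert pred["posterior_I"].iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert pred["predicted"].iloc[0] == "A"

    def test_error_rate_near_analytic_bayes_error(self):
        # equal-variance Gaussian classes at Mahalanobis distance delta
        # have Bayes accuracy Phi(delta / 2)
        mix = make_single_gaussian_mixtures(0.0, 1.0, 1.0)
        n = 1000
        train = pd.concat([
            sample_feature_matrix(mix, 5000, "A", 10),
            sample_feature_matrix(mix, 5000, "I", 11)],
            ignore_index=True)
        test = pd.concat([
            sample_feature_matrix(mix, n // 2, "A", 12),
            sample_feature_matrix(mix, n // 2, "I", 13)],
            ignore_index=True)
        model = train_gnb(train)
        pred = predict_nb(model, test)
        acc = float(np.mean(pred["predicted"] == test["label"]))
        delta = np.sqrt(8 * 1.0)  # 8 features, unit sd, unit mean gap
        bayes = norm.cdf(delta / 2)
        se = np.sqrt(bayes * (1 - bayes) / n)
        assert abs(acc - bayes) < 3 * se

    def test_zero_variance_feature_rejected(self):
        X = np.ones((4, 8))
        X[2:, 0] = 5.0
        df = labeled_frame(X, ["A", "A", "I", "I"])
        with pytest.raises(ValueError, match="zero variance"):
            train_gnb(df)

    def test_posterior_invariant_to_feature_permutation(self, rng):
        X = rng.normal(0, 1, (100, 8))
        labels = np.repeat(["A", "I"], 50)
        X[labels == "I"] += 0.8
        df = labeled_frame(X, labels)
        perm = rng.permutation(8)
        df_perm = labeled_frame(X[:, perm], labels)
        p1 = predict_nb(train_gnb(df), df)
        p2 = predict_nb(train_gnb(df_perm), df_perm)
        np.testing.assert_allclose(p1["posterior_I"], p2["posterior_I"],
                                   atol=1e-12)


class TestKNB:
    def test_posterior_matches_kde_oracle(self, rng):
        X = rng.normal(0, 1, (80, 8))
        labels = np.repeat(["A", "I"], 40)
        X[labels == "I"] += 1.2
        df = labeled_frame(X, labels)
        model = train_knb(df)
        pred = predict_nb(model, df)
        oracle = knb_oracle_posterior(model, X)
        np.testing.assert_allclose(pred["posterior_I"].to_numpy(), oracle,
                                   atol=1e-10)

    def test_normal_reference_bandwidth(self, rng):
        X = rng.normal(0, 1, (50, 8))
        labels = np.repeat(["A", "I"], 25)
        df = labeled_frame(X, labels)
        model = train_knb(df)
        sd = X[:25].std(axis=0, ddof=1)
        np.testing.assert_allclose(model.bandwidths[0],
                                   1.06 * sd * 25 ** (-0.2))

    def test_kde_density_integrates_to_one(self, rng):
        X = rng.normal(3.0, 2.0, (30, 8))
        labels = np.repeat(["A", "I"], 15)
        df = labeled_frame(X, labels)
        model = train_knb(df)
        lo, hi = 3.0 - 20.0, 3.0 + 20.0
        integral, _ = quad(
            lambda x: float(np.exp(model.feature_log_density("A", 0, x))[0]),
            lo, hi, limit=200)
        assert 0.999 <= integral <= 1.001

    def test_bimodal_class_favors_kde_over_gaussian(self, rng):
        # class A bimodal at +/-4, class I unimodal at 0: a single
        # Gaussian fit to A swallows I, the KDE does not
        n = 200
        x_a = np.concatenate([rng.normal(-4, 0.5, n // 2),
                              rng.normal(4, 0.5, n // 2)])
        x_i = rng.normal(0, 0.5, n)
        X = np.zeros((2 * n, 8))
        X[:, 0] = np.concatenate([x_a, x_i])
        X[:, 1:] = rng.normal(0, 1, (2 * n, 7))
        labels = np.repeat(["A", "I"], n)
        df = labeled_frame(X, labels)
        acc_gnb = float(np.mean(
            predict_nb(train_gnb(df), df)["predicted"] == labels))
        acc_knb = float(np.mean(
            predict_nb(train_knb(df), df)["predicted"] == labels))
        assert acc_knb >= acc_gnb
        assert acc_knb > 0.95


class TestSVM:
    def test_separable_toy_set_trains_cleanly(self):
        X = np.zeros((4, 8))
        X[:, 0] = [-2.0, -1.5, 1.5, 2.0]
        df = labeled_frame(X, ["A", "A", "I", "I"])
        model = train_svm(df, sigma=1.0, C=100.0)
        assert (model.predict(df)["predicted"] == df["label"]).all()

    def test_presets(self):
        assert SVM_PRESETS["coarse"] == (11.0, 1.0)
        assert SVM_PRESETS["medium"] == (2.8, 1.0)
        assert SVM_PRESETS["fine"] == (0.71, 1.0)
        X = np.zeros((8, 8))
        X[:, 0] = [-3, -2, -2.5, -1.5, 1.5, 2, 2.5, 3]
        df = labeled_frame(X, ["A"] * 4 + ["I"] * 4)
        model = train_svm(df, preset="medium")
        assert (model.sigma, model.C) == (2.8, 1.0)

    @pytest.mark.parametrize("seed,sigma,C", [(3, 2.8, 1.0), (9, 1.0, 5.0)])
    def test_decision_matches_dense_qp_oracle(self, seed, sigma, C):
        rng = np.random.default_rng(seed)
        n = 8
        X = np.vstack([rng.normal(0, 1, (n, 8)),
                       rng.normal(1.2, 1, (n, 8))])
        y = np.array([-1] * n + [1] * n)
        df = labeled_frame(X, np.where(y > 0, "I", "A"))
        model = train_svm(df, sigma=sigma, C=C, tol=1e-10)
        Z = (X - X.mean(0)) / X.std(0)
        alpha, bias, K = svm_qp_oracle(Z, y, sigma, C)
        oracle_decision = (alpha * y) @ K + bias
        np.testing.assert_allclose(model.decision_function(df),
                                   oracle_decision, atol=1e-6)
        assert np.all(np.abs(model.dual_coef) <= C + 1e-9)

    def test_prediction_invariant_to_feature_rescaling(self, rng):
        X = rng.normal(0, 1, (60, 8))
        labels = np.repeat(["A", "I"], 30)
        X[labels == "I", :2] += 1.5
        df = labeled_frame(X, labels)
        scaled = X.copy()
        scaled[:, 3] = 50.0 * scaled[:, 3] - 7.0
        df_scaled = labeled_frame(scaled, labels)
        d1 = train_svm(df, preset="medium").decision_function(df)
        d2 = train_svm(df_scaled, preset="medium").decision_function(
            df_scaled)
        np.testing.assert_allclose(d1, d2, atol=1e-8)


class TestHyperparameterSearch:
    def make_data(self, rng):
        X = rng.normal(0, 1, (80, 8))
        labels = np.repeat(["A", "I"], 40)
        X[labels == "I"] += 1.2
        return labeled_frame(X, labels)

    def test_single_iteration_returns_only_candidate(self, rng):
        df = self.make_data(rng)
        sigma, C, traj = search_hyperparameters(df, n_iter=1, rng_seed=4)
        assert len(traj) == 1
        assert (sigma, C) == (traj["sigma"].iloc[0], traj["C"].iloc[0])

    def test_selected_pair_minimizes_evaluated_cv_error(self, rng):
        df = self.make_data(rng)
        sigma, C, traj = search_hyperparameters(df, n_iter=6, rng_seed=4)
        best = traj.loc[traj["cv_error"].idxmin()]
        assert (sigma, C) == (best["sigma"], best["C"])
        assert (traj["cv_error"] >= best["cv_error"] - 1e-12).all()
        lo, hi = 1e-3, 1e3
        assert traj["sigma"].between(lo, hi).all()
        assert traj["C"].between(lo, hi).all()

    def test_same_seed_same_trajectory(self, rng):
        df = self.make_data(rng)
        _, _, t1 = search_hyperparameters(df, n_iter=3, rng_seed=8)
        _, _, t2 = search_hyperparameters(df, n_iter=3, rng_seed=8)
        pd.testing.assert_frame_equal(t1, t2)


class TestSerialization:
    @pytest.mark.parametrize("kind", ["gnb", "knb", "svm"])
    def test_json_round_trip_preserves_predictions(self, kind, rng,
                                                   tmp_path):
        X = rng.normal(0, 1, (60, 8))
        labels = np.repeat(["A", "I"], 30)
        X[labels == "I"] += 1.5
        df = labeled_frame(X, labels)
        if kind == "gnb":
            model, predictor = train_gnb(df), predict_nb
        elif kind == "knb":
            model, predictor = train_knb(df), predict_nb
        else:
            model = train_svm(df, preset="fine")
            predictor = lambda m, d: m.predict(d)
        path = tmp_path / f"{kind}.json"
        save_model(model, path)
        reloaded = load_model(path)
        p1 = predictor(model, df)
        p2 = predictor(reloaded, df)
        assert (p1["predicted"] == p2["predicted"]).all()
        value_col = "posterior_I" if kind != "svm" else "decision"
        np.testing.assert_allclose(p1[value_col], p2[value_col], atol=1e-12)
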