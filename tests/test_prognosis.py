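"""Logistic LASSO, signature construction, and cross-validation."""

import numpy as np
import pytest

import omicsig as og
from omicsig.prognosis import (LogisticLassoFit, _balanced_class_bootstrap,
                               _stratified_folds, logistic_lambda_max,
                               logistic_lasso_fit)


def make_logistic_instance(seed, n=80, p=5, strength=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = strength * X[:, 0] - strength * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return X, y


class TestLogisticLasso:
    def test_heavy_penalty_gives_log_odds_intercept(self):
        X, y = make_logistic_instance(0)
        lam = 10 * logistic_lambda_max(X, y)
        fit = logistic_lasso_fit(X, y, lam)
        np.testing.assert_array_equal(fit.coefficients, 0.0)
        assert fit.intercept == pytest.approx(
            np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_unpenalized_matches_newton_logistic(self):
        # 1-D, non-separable toy printed inline
        X = np.array([[-2.0], [-1.0], [-0.5], [0.3], [0.4], [1.1], [2.0],
                      [-0.2]])
        y = np.array([0.0, 0, 1, 0, 1, 1, 1, 0])
        fit = logistic_lasso_fit(X, y, 0.0, tol=1e-12, max_iter=50000)
        # independent Newton–Raphson oracle
        b = np.zeros(2)
        A = np.hstack([np.ones((8, 1)), X])
        for _ in range(100):
            eta = A @ b
            mu = 1 / (1 + np.exp(-eta))
            W = mu * (1 - mu)
            grad = A.T @ (mu - y)
            H = A.T @ (A * W[:, None])
            step = np.linalg.solve(H, grad)
            b -= step
            if np.max(np.abs(step)) < 1e-12:
                break
        assert fit.intercept == pytest.approx(b[0], abs=1e-5)
        assert fit.coefficients[0] == pytest.approx(b[1], abs=1e-5)

    def test_objective_matches_sklearn_saga(self):
        from sklearn.linear_model import LogisticRegression
        for seed in range(5):
            X, y = make_logistic_instance(seed, n=100, p=6)
            lam = 0.02
            fit = logistic_lasso_fit(X, y, lam, tol=1e-12, max_iter=30000)
            n = len(y)
            sk = LogisticRegression(penalty="l1", C=1.0 / (n * lam),
                                    solver="saga", tol=1e-10,
                                    max_iter=100000).fit(X, y)

            def obj(b, b0):
                eta = b0 + X @ b
                return (np.mean(np.logaddexp(0, eta) - y * eta)
                        + lam * np.abs(b).sum())

            ours = obj(fit.coefficients, fit.intercept)
            theirs = obj(sk.coef_[0], sk.intercept_[0])
            assert ours <= theirs + 1e-6

    def test_single_class_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="both classes"):
            logistic_lasso_fit(X, np.zeros(4), 0.1)


class TestMetrics:
    def test_perfect_and_inverted_confusions(self):
        assert og.classification_metrics(5, 0, 5, 0) == (1.0, 0.0, 1.0)
        acc, err, mcc = og.classification_metrics(0, 5, 0, 5)
        assert (acc, err, mcc) == (0.0, 1.0, -1.0)

    def test_matches_sklearn_on_random_tables(self, rng):
        from sklearn.metrics import accuracy_score, matthews_corrcoef
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 20, 4)
            if tp + fp + tn + fn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            acc, err, mcc = og.classification_metrics(tp, fp, tn, fn)
            assert acc == pytest.approx(accuracy_score(y_true, y_pred))
            assert err == pytest.approx(1 - acc)
            assert mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_label_swap_symmetry(self, rng):
        for _ in range(10):
            tp, fp, tn, fn = rng.integers(1, 20, 4)
            _, _, mcc = og.classification_metrics(tp, fp, tn, fn)
            _, _, mcc_swapped = og.classification_metrics(tn, fn, tp, fp)
            assert mcc == pytest.approx(mcc_swapped)
            assert -1 <= mcc <= 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            og.classification_metrics(0, 0, 0, 0)


FAST_SIG = dict(n_bootstrap=15, seed=0)


class TestBuildSignature:
    def test_zero_sizes_give_intercept_only(self, small_cohort):
        cohort, _ = small_cohort
        de = og.screen_de_features(cohort)
        cfg = og.SignatureConfig(layer_sizes={"mRNA": 0, "protein": 0},
                                 **FAST_SIG)
        model = og.build_signature(cohort, de, cfg)
        assert len(model.coefficients) == 0
        y = (cohort.group_labels() == "poor").mean()
        assert model.intercept == pytest.approx(np.log(y / (1 - y)))

    def test_layer_sizes_realized_exactly(self, small_cohort):
        cohort, _ = small_cohort
        de = og.screen_de_features(cohort)
        assert len(de["mRNA"]) >= 6 and len(de["protein"]) >= 3
        cfg = og.SignatureConfig(layer_sizes={"mRNA": 6, "protein": 3},
                                 **FAST_SIG)
        model = og.build_signature(cohort, de, cfg)
        assert len(model.layer_features["mRNA"]) == 6
        assert len(model.layer_features["protein"]) == 3

    def test_small_layer_keeps_all_with_warning(self, small_cohort):
        cohort, _ = small_cohort
        de = {"mRNA": ["mRNA_0000", "mRNA_0001"], "protein": []}
        cfg = og.SignatureConfig(layer_sizes={"mRNA": 10, "protein": 0},
                                 **FAST_SIG)
        with pytest.warns(UserWarning, match="keeping all"):
            model = og.build_signature(cohort, de, cfg)
        assert len(model.layer_features["mRNA"]) == 2

    def test_kept_features_are_planted_risk_features(self):
        """When the hazard-driving features are the DE set, the kept
        features overwhelmingly come from the planted truth."""
        hits, total = 0, 0
        for seed in range(3):
            cfg = og.SimConfig(n_samples=200, features_per_layer={"mRNA": 60},
                               de_fraction=0.25, de_effect=2.0,
                               edge_effect_range=(0.0, 0.0),
                               risk_features_per_layer=15, seed=seed)
            cohort, truth = og.simulate_cohort(cfg)
            de = og.screen_de_features(cohort)
            sig_cfg = og.SignatureConfig(layer_sizes={"mRNA": 10},
                                         n_bootstrap=15, seed=seed)
            model = og.build_signature(cohort, de, sig_cfg)
            kept = model.layer_features["mRNA"]
            true_de = set(truth.de_features["mRNA"])
            hits += len(set(kept) & true_de)
            total += len(kept)
        assert hits / total >= 0.7


class TestCrossValidate:
    def test_separable_signal_classified_perfectly(self):
        cfg = og.SimConfig(n_samples=100, features_per_layer={"mRNA": 30},
                           de_fraction=0.3, de_effect=6.0,
                           edge_effect_range=(0.0, 0.0), seed=1)
        cohort, _ = og.simulate_cohort(cfg)
        rep = og.cross_validate(
            cohort, og.SignatureConfig(layer_sizes={"mRNA": 8}, **FAST_SIG),
            k=3, seed=1)
        assert rep.accuracy == 1.0
        assert rep.mcc == 1.0
        assert rep.error_rate == 0.0

    def test_permuted_labels_fall_to_chance(self):
        cfg = og.SimConfig(n_samples=100, features_per_layer={"mRNA": 30},
                           de_fraction=0.3, de_effect=2.0,
                           edge_effect_range=(0.0, 0.0), seed=2)
        cohort, _ = og.simulate_cohort(cfg)
        rng = np.random.default_rng(0)
        clin = cohort.clinical.copy()
        clin["group"] = rng.permutation(clin["group"].to_numpy())
        shuffled = og.Cohort(cohort.layers, clin)
        rep = og.cross_validate(
            shuffled, og.SignatureConfig(layer_sizes={"mRNA": 8}, **FAST_SIG),
            k=3, seed=2)
        n = len(clin)
        majority = max(clin["group"].value_counts()) / n
        assert rep.accuracy <= majority + 3 * np.sqrt(0.25 / n)

    def test_bitwise_reproducible_given_seed(self, small_cohort):
        cohort, _ = small_cohort
        cfg = og.SignatureConfig(layer_sizes={"mRNA": 5, "protein": 3},
                                 **FAST_SIG)
        r1 = og.cross_validate(cohort, cfg, k=3, seed=5)
        r2 = og.cross_validate(cohort, cfg, k=3, seed=5)
        assert r1.accuracy == r2.accuracy
        assert r1.fold_confusions == r2.fold_confusions
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_accuracy_monotone_in_effect_size(self):
        accs = {}
        for effect in (0.5, 2.0):
            vals = []
            for seed in range(3):
                cfg = og.SimConfig(n_samples=120,
                                   features_per_layer={"mRNA": 30},
                                   de_fraction=0.3, de_effect=effect,
                                   edge_effect_range=(0.0, 0.0), seed=seed)
                cohort, _ = og.simulate_cohort(cfg)
                rep = og.cross_validate(
                    cohort,
                    og.SignatureConfig(layer_sizes={"mRNA": 8}, n_bootstrap=15,
                                       seed=seed),
                    k=3, seed=seed)
                vals.append(rep.accuracy)
            accs[effect] = np.mean(vals)
        assert accs[2.0] >= accs[0.5]

    def test_k_larger_than_class_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="class size"):
            og.cross_validate(cohort, og.SignatureConfig(**FAST_SIG), k=1000)


class TestHelpers:
    def test_balanced_bootstrap_equalizes_classes(self, rng):
        y = np.array([0] * 30 + [1] * 10)
        idx = _balanced_class_bootstrap(y, rng)
        resampled = y[idx]
        assert (resampled == 0).sum() == (resampled == 1).sum() == 30

    def test_stratified_folds_preserve_both_classes(self, rng):
        y = np.array([0] * 20 + [1] * 15)
        folds = _stratified_folds(y, 5, rng)
        assert sorted(np.concatenate(folds)) == list(range(35))
        for f in folds:
            assert len(np.unique(y[f])) == 2
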