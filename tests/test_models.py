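"""Classifier registry, metric panel, and the GP/EI optimizer."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from vmdeeg.models import (
    REGISTRY,
    SEARCH_SPACES,
    BayesSearchClassifier,
    Categorical,
    ClassifierSpec,
    Integer,
    OptimizationConfig,
    Real,
    bayes_optimize,
    estimator_from_params,
    evaluate,
    gp_minimize,
    report_from_confusion,
    train,
)


def _blobs(n=80, sep=3.0, seed=0):
    X, y = make_blobs(n_samples=n, centers=[[-sep, 0.0], [sep, 0.0]],
                      cluster_std=1.0, random_state=seed)
    return X, y


class TestTrain:
    @pytest.mark.parametrize("family,variant", [
        ("decision_tree", "fine"), ("lda", "default"), ("logistic", "default"),
        ("naive_bayes", "default"), ("svm", "quadratic"), ("svm", "cubic"),
        ("knn", "fine"), ("ensemble", "bagged_trees"),
        ("ensemble", "subspace_knn"), ("mlp", "narrow"),
    ])
    def test_separable_blobs(self, family, variant):
        X, y = _blobs(sep=4.0)
        model = train(ClassifierSpec(family, variant), X, y, seed=0)
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_knn1_self_accuracy(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.array([0, 1] * 20)
        model = train(ClassifierSpec("knn", "fine"), X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train(ClassifierSpec("lda"), np.zeros((10, 2)), np.zeros(10))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            ClassifierSpec("svm", "quartic")

    def test_permutation_null(self):
        """Labels shuffled independently of X: CV accuracy hovers at chance."""
        from vmdeeg.dataset import FeatureTable
        from vmdeeg.features import feature_names
        from vmdeeg.validation import kfold_cv

        rng = np.random.default_rng(0)
        accs = []
        names = feature_names(["F3"], 1)[:4]
        for seed in range(10):
            X = rng.standard_normal((60, 4))
            y = rng.permutation([0, 1] * 30)
            tab = FeatureTable(X, y, np.arange(60).astype(str), names[:4])
            accs.append(kfold_cv(ClassifierSpec("lda"), tab, k=10,
                                 seed=seed).accuracy)
        assert 40.0 <= np.mean(accs) <= 60.0


class TestEvaluationMetrics:
    def test_perfect_predictions(self):
        rep = report_from_confusion(tn=50, fp=0, fn=0, tp=50)
        assert (rep.accuracy, rep.sensitivity, rep.specificity,
                rep.precision, rep.f1) == (100.0,) * 5

    def test_f1_from_published_ensemble_row(self):
        """F1 reproduces from SE/PR of a reported optimized-ensemble result."""
        se, pr = 99.52, 98.58
        f1 = 2 * pr * se / (pr + se)
        assert round(f1, 2) == 99.05
        rep = report_from_confusion(tn=98.57, fp=1.43, fn=0.48, tp=99.52)
        assert rep.f1 == pytest.approx(f1, abs=0.02)

    def test_f1_from_published_cubic_svm_row(self):
        se, pr = 97.62, 98.80
        assert round(2 * pr * se / (pr + se), 2) == 98.21

    def test_all_negative_predictor(self):
        with pytest.warns(UserWarning, match="precision sentinel"):
            rep = report_from_confusion(tn=50, fp=0, fn=50, tp=0)
        assert rep.accuracy == 50.0
        assert rep.sensitivity == 0.0
        assert rep.specificity == 100.0
        assert rep.precision == 0.0

    def test_balanced_identity(self, rng):
        """On balanced data Ac == (SE+SP)/2 and F1 is the PR/SE harmonic mean."""
        X, y = _blobs(n=100, sep=2.0)
        model = train(ClassifierSpec("logistic"), X, y)
        rep = evaluate(model, X, y)
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2, abs=1e-9)
        assert rep.f1 == pytest.approx(
            2 * rep.precision * rep.sensitivity
            / (rep.precision + rep.sensitivity), abs=1e-9)

    def test_roc_present(self):
        X, y = _blobs()
        model = train(ClassifierSpec("svm", "linear"), X, y)
        rep = evaluate(model, X, y)
        assert rep.auc > 0.9
        assert rep.roc_fpr.size == rep.roc_tpr.size > 2


class TestGpMinimize:
    def test_quadratic_minimum_found(self):
        best, loss, trace = gp_minimize(lambda p: (p["x"] - 0.3) ** 2,
                                        [Real("x", 0.0, 1.0)],
                                        n_iterations=30, seed=1)
        assert abs(best["x"] - 0.3) <= 0.05
        assert len(trace) == 30

    def test_best_so_far_non_increasing(self):
        _, _, trace = gp_minimize(lambda p: (p["x"] - 0.7) ** 2,
                                  [Real("x", 0.0, 1.0)], n_iterations=20,
                                  seed=3)
        losses = [l for _, l in trace]
        running = np.minimum.accumulate(losses)
        assert np.all(np.diff(running) <= 0)

    def test_budget_respected(self):
        calls = []

        def f(p):
            calls.append(p)
            return p["x"] ** 2

        gp_minimize(f, [Real("x", 0.0, 1.0)], n_iterations=12, seed=0)
        assert len(calls) == 12

    def test_deterministic_trace(self):
        args = (lambda p: np.sin(5 * p["x"]) + p["x"] ** 2,
                [Real("x", 0.0, 1.0)])
        out1 = gp_minimize(*args, n_iterations=15, seed=9)
        out2 = gp_minimize(*args, n_iterations=15, seed=9)
        assert out1[0] == out2[0]
        assert [l for _, l in out1[2]] == [l for _, l in out2[2]]

    def test_mixed_space_decoding(self):
        space = [Real("a", 1e-3, 1e3, log=True), Integer("k", 1, 30),
                 Categorical("m", ("u", "v", "w"))]
        best, _, trace = gp_minimize(
            lambda p: abs(np.log10(p["a"])) + abs(p["k"] - 7) / 30
            + (p["m"] != "v"), space, n_iterations=25, seed=2)
        for params, _ in trace:
            assert 1e-3 <= params["a"] <= 1e3
            assert 1 <= params["k"] <= 30
            assert params["m"] in ("u", "v", "w")

    def test_invalid_space(self):
        with pytest.raises(ValueError):
            Real("x", 2.0, 1.0)
        with pytest.raises(ValueError):
            gp_minimize(lambda p: 0.0, [], n_iterations=5, seed=0)


class TestBayesOptimize:
    def test_knn_improves_over_median_random_search(self):
        """The GP-guided search matches or beats the median random-search
        result at equal budget on a moderately hard problem."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 10))
        y = (X[:, 0] + 0.5 * rng.standard_normal(80) > 0).astype(int)
        wins = 0
        for seed in range(5):
            cfg = OptimizationConfig(n_iterations=15, n_folds=5, seed=seed)
            _, bo_loss, _ = bayes_optimize("knn", X, y, cfg)
            space = SEARCH_SPACES["knn"]
            r = np.random.default_rng(seed)
            rand_losses = []
            from vmdeeg.models import _cv_loss, _decode_point

            for _ in range(15):
                params = _decode_point(r.random(len(space)), space)
                est = estimator_from_params("knn", params, seed, 10)
                rand_losses.append(_cv_loss(est, X, y, 5, seed))
            if bo_loss <= np.median(rand_losses):
                wins += 1
        assert wins >= 3

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            bayes_optimize("quantum", np.zeros((10, 2)),
                           np.array([0, 1] * 5))


class TestBayesSearchClassifier:
    def test_sklearn_api(self):
        X, y = _blobs(sep=4.0)
        clf = BayesSearchClassifier("knn", n_iterations=8, n_folds=4, seed=0)
        assert clf.get_params()["family"] == "knn"
        clf.fit(X, y)
        assert hasattr(clf, "best_params_")
        assert hasattr(clf, "best_estimator_")
        assert len(clf.trace_) == 8
        assert clf.score(X, y) >= 0.9

    def test_clone_compatible(self):
        from sklearn.base import clone

        clf = BayesSearchClassifier("svm", n_iterations=5, seed=2)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()

    @pytest.mark.parametrize("family", sorted(SEARCH_SPACES))
    def test_every_family_space_instantiates(self, family):
        """Every search-space corner decodes into a fit-able estimator."""
        space = SEARCH_SPACES[family]
        rng = np.random.default_rng(0)
        X, y = _blobs(n=40, sep=4.0)
        for u in (np.zeros(len(space)), np.ones(len(space)) - 1e-9,
                  rng.random(len(space))):
            from vmdeeg.models import _decode_point

            params = _decode_point(u, space)
            est = estimator_from_params(family, params, 0, X.shape[1])
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X, y)
            est.predict(X)
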