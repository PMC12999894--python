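"""Classifier suite and Bayesian hyperparameter optimization.

The registry mirrors the naming of common EEG classification suites: tree
presets (fine/medium/coarse), discriminant, logistic, naive Bayes, SVM kernels
(linear/quadratic/cubic and fine/medium/coarse Gaussian), KNN presets,
ensembles (bagged/boosted trees, random-subspace KNN/discriminant) and small
MLPs.  "Optimizable" variants tune each family's hyperparameters by Gaussian-
process surrogate optimization with the expected-improvement acquisition,
minimizing stratified k-fold cross-validation misclassification with
fold-internal z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "OptimizationConfig",
    "EvaluationReport",
    "Real",
    "Integer",
    "Categorical",
    "make_classifier",
    "train",
    "decision_scores",
    "evaluate",
    "gp_minimize",
    "bayes_optimize",
    "BayesSearchClassifier",
    "SEARCH_SPACES",
    "REGISTRY",
]

FAMILIES = ("decision_tree", "lda", "logistic", "naive_bayes", "svm", "knn",
            "ensemble", "mlp")


@dataclass(frozen=True)
class ClassifierSpec:
    """One (family, variant) entry of the classifier registry."""

    family: str
    variant: str = "default"
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.family, self.variant) not in REGISTRY:
            raise ValueError(
                f"unsupported classifier {self.family}/{self.variant}; "
                f"known: {sorted(REGISTRY)}"
            )


def _svc(kernel: str, seed: int, *, degree: int = 3, gamma: Any = "scale",
         C: float = 1.0) -> SVC:
    # coef0=1: inhomogeneous polynomial kernel (1 + <x,y>)^q, the usual
    # "quadratic"/"cubic" preset convention
    return SVC(kernel=kernel, degree=degree, gamma=gamma, C=C, coef0=1.0,
               random_state=seed, probability=False)


def _gamma_from_scale(scale_mult: float) -> Callable[[np.ndarray], float]:
    # Gaussian presets use kernel scale s = scale_mult * sqrt(d); gamma = 1/s^2.
    def g(X: np.ndarray) -> float:
        d = X.shape[1]
        return 1.0 / (scale_mult ** 2 * d)

    return g


# Builders take (seed, n_features) so data-dependent kernel scales resolve at
# fit time.  Tree presets cap leaf counts the way "fine/medium/coarse" presets
# commonly do (max splits 100 / 20 / 4).
REGISTRY: dict[tuple[str, str], Callable[[int, int], BaseEstimator]] = {
    ("decision_tree", "fine"): lambda s, d: DecisionTreeClassifier(max_leaf_nodes=101, random_state=s),
    ("decision_tree", "medium"): lambda s, d: DecisionTreeClassifier(max_leaf_nodes=21, random_state=s),
    ("decision_tree", "coarse"): lambda s, d: DecisionTreeClassifier(max_leaf_nodes=5, random_state=s),
    ("decision_tree", "default"): lambda s, d: DecisionTreeClassifier(max_leaf_nodes=21, random_state=s),
    ("lda", "default"): lambda s, d: LinearDiscriminantAnalysis(),
    ("logistic", "default"): lambda s, d: LogisticRegression(max_iter=2000, random_state=s),
    ("naive_bayes", "default"): lambda s, d: GaussianNB(),
    ("svm", "linear"): lambda s, d: _svc("linear", s),
    ("svm", "quadratic"): lambda s, d: _svc("poly", s, degree=2),
    ("svm", "cubic"): lambda s, d: _svc("poly", s, degree=3),
    ("svm", "rbf"): lambda s, d: _svc("rbf", s),
    ("svm", "fine_gaussian"): lambda s, d: _svc("rbf", s, gamma=16.0 / d),
    ("svm", "medium_gaussian"): lambda s, d: _svc("rbf", s, gamma=1.0 / d),
    ("svm", "coarse_gaussian"): lambda s, d: _svc("rbf", s, gamma=1.0 / (16.0 * d)),
    ("svm", "default"): lambda s, d: _svc("rbf", s),
    ("knn", "fine"): lambda s, d: KNeighborsClassifier(n_neighbors=1),
    ("knn", "medium"): lambda s, d: KNeighborsClassifier(n_neighbors=10),
    ("knn", "coarse"): lambda s, d: KNeighborsClassifier(n_neighbors=100),
    ("knn", "cosine"): lambda s, d: KNeighborsClassifier(n_neighbors=10, metric="cosine"),
    ("knn", "cubic"): lambda s, d: KNeighborsClassifier(n_neighbors=10, metric="minkowski", p=3),
    ("knn", "weighted"): lambda s, d: KNeighborsClassifier(n_neighbors=10, weights="distance"),
    ("knn", "default"): lambda s, d: KNeighborsClassifier(n_neighbors=10),
    ("ensemble", "bagged_trees"): lambda s, d: BaggingClassifier(
        DecisionTreeClassifier(random_state=s), n_estimators=30, random_state=s),
    ("ensemble", "boosted_trees"): lambda s, d: AdaBoostClassifier(
        DecisionTreeClassifier(max_depth=1, random_state=s), n_estimators=30,
        learning_rate=0.1, random_state=s),
    ("ensemble", "subspace_knn"): lambda s, d: BaggingClassifier(
        KNeighborsClassifier(n_neighbors=5), n_estimators=30,
        max_features=0.5, bootstrap=False, random_state=s),
    ("ensemble", "subspace_discriminant"): lambda s, d: BaggingClassifier(
        LinearDiscriminantAnalysis(), n_estimators=30, max_features=0.5,
        bootstrap=False, random_state=s),
    ("ensemble", "default"): lambda s, d: BaggingClassifier(
        DecisionTreeClassifier(random_state=s), n_estimators=30, random_state=s),
    ("mlp", "narrow"): lambda s, d: MLPClassifier((10,), max_iter=800, random_state=s),
    ("mlp", "medium"): lambda s, d: MLPClassifier((25,), max_iter=800, random_state=s),
    ("mlp", "wide"): lambda s, d: MLPClassifier((100,), max_iter=800, random_state=s),
    ("mlp", "bilayered"): lambda s, d: MLPClassifier((10, 10), max_iter=800, random_state=s),
    ("mlp", "trilayered"): lambda s, d: MLPClassifier((10, 10, 10), max_iter=800, random_state=s),
    ("mlp", "default"): lambda s, d: MLPClassifier((25,), max_iter=800, random_state=s),
}


def make_classifier(spec: ClassifierSpec, n_features: int, seed: int = 0) -> BaseEstimator:
    est = REGISTRY[(spec.family, spec.variant)](seed, max(n_features, 1))
    if spec.fixed_params:
        est.set_params(**spec.fixed_params)
    return est


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if not np.isfinite(X).all():
        raise ValueError("X contains NaN/Inf")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    return X, y


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0) -> BaseEstimator:
    """Fit the registry classifier; the result supports predict and
    decision scores for ROC."""
    X, y = _check_xy(X, y)
    est = make_classifier(spec, X.shape[1], seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        est.fit(X, y)
    return est


def decision_scores(model: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """Continuous scores for the positive class (for ROC)."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, -1]
    return np.asarray(model.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Metric panel with SCH (label 1) as the positive class.

    Confusion matrix layout [[TN, FP], [FN, TP]]; all rates in percent.
    """

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    roc_fpr: np.ndarray = field(default_factory=lambda: np.empty(0))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.empty(0))
    auc: float = float("nan")
    per_fold_accuracy: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "per_fold_accuracy": self.per_fold_accuracy,
        }


def report_from_confusion(
    tn: float, fp: float, fn: float, tp: float,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
    per_fold_accuracy: Sequence[float] = (),
) -> EvaluationReport:
    """Metric panel from confusion counts (and optional ROC scores).

    Precision is 0 (logged) when nothing was predicted positive.
    """
    n = tn + fp + fn + tp
    ac = 100.0 * (tp + tn) / n
    se = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    if tp + fp:
        pr = 100.0 * tp / (tp + fp)
    else:
        warnings.warn("degenerate predictions: no positive predictions; "
                      "precision sentinel 0", UserWarning, stacklevel=2)
        pr = 0.0
    f1 = 2 * pr * se / (pr + se) if pr + se else 0.0
    fpr = tpr = np.empty(0)
    auc = float("nan")
    if scores is not None and y_true is not None and len(np.unique(y_true)) == 2:
        fpr, tpr, _ = roc_curve(y_true, scores)
        auc = float(roc_auc_score(y_true, scores))
    return EvaluationReport(
        confusion=np.array([[tn, fp], [fn, tp]], dtype=float),
        accuracy=ac, sensitivity=se, specificity=sp, precision=pr, f1=f1,
        roc_fpr=fpr, roc_tpr=tpr, auc=auc,
        per_fold_accuracy=list(per_fold_accuracy),
    )


def evaluate(model: BaseEstimator, X: np.ndarray, y: np.ndarray) -> EvaluationReport:
    """Metric panel of a fitted model on (X, y)."""
    X, y = _check_xy(X, y)
    pred = np.asarray(model.predict(X)).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return report_from_confusion(tn, fp, fn, tp, decision_scores(model, X), y)


# ---------------------------------------------------------------------------
# Gaussian-process Bayesian optimization (expected improvement)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: need low < high")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log scale needs positive bounds")

    def decode(self, u: float) -> float:
        if self.log:
            lo, hi = np.log10(self.low), np.log10(self.high)
            return float(10 ** (lo + u * (hi - lo)))
        return float(self.low + u * (self.high - self.low))


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int
    log: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: need low < high")

    def decode(self, u: float) -> int:
        if self.log:
            lo, hi = np.log10(self.low), np.log10(self.high)
            return int(round(10 ** (lo + u * (hi - lo))))
        return int(round(self.low + u * (self.high - self.low)))


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple

    def decode(self, u: float):
        idx = min(int(u * len(self.choices)), len(self.choices) - 1)
        return self.choices[idx]


Dimension = Real | Integer | Categorical


def _decode_point(u: np.ndarray, space: Sequence[Dimension]) -> dict:
    return {dim.name: dim.decode(float(v)) for dim, v in zip(space, u)}


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float,
                          xi: float = 0.01) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    imp = best - mu - xi
    z = imp / sigma
    return imp * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


@dataclass
class OptimizationConfig:
    """Budget and protocol of the Bayesian search.

    n_iterations : total objective evaluations (initial design included).
    n_folds : stratified CV folds of the inner objective.
    n_initial : quasi-random points before the surrogate takes over.
    xi : EI exploration parameter.
    """

    n_iterations: int = 30
    n_folds: int = 10
    n_initial: int = 5
    xi: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def gp_minimize(
    func: Callable[[dict], float],
    space: Sequence[Dimension],
    n_iterations: int = 30,
    seed: int = 0,
    n_initial: int = 5,
    xi: float = 0.01,
    n_candidates: int = 256,
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Minimize ``func`` over ``space`` with a GP surrogate and EI acquisition.

    Exactly ``n_iterations`` objective evaluations are made: a seeded Sobol
    initial design of ``min(n_initial, n_iterations)`` points, then EI-chosen
    proposals (EI maximized over a seeded candidate set).  Returns
    (best_params, best_loss, trace); earliest iteration wins ties.
    """
    if not space:
        raise ValueError("empty search space")
    d = len(space)
    rng = np.random.default_rng(seed)
    sob = stats.qmc.Sobol(d, scramble=True, rng=np.random.default_rng(seed))
    n_init = min(n_initial, n_iterations)
    U = [np.clip(sob.random(1)[0], 0, 1 - 1e-12) for _ in range(n_init)]

    trace: list[tuple[dict, float]] = []
    evals_u: list[np.ndarray] = []
    losses: list[float] = []

    def run(u: np.ndarray) -> None:
        params = _decode_point(u, space)
        loss = float(func(params))
        evals_u.append(u)
        losses.append(loss)
        trace.append((params, loss))

    for u in U:
        run(u)

    kernel = Matern(length_scale=np.full(d, 0.25), nu=2.5,
                    length_scale_bounds=(1e-2, 1e1))
    for _ in range(n_init, n_iterations):
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-8, normalize_y=True,
            n_restarts_optimizer=1, random_state=int(rng.integers(2 ** 31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.vstack(evals_u), np.asarray(losses))
        cand = rng.random((n_candidates, d))
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, min(losses), xi)
        run(cand[int(np.argmax(ei))])

    best_idx = int(np.argmin(losses))  # argmin returns the earliest tie
    return trace[best_idx][0], losses[best_idx], trace


# Per-family search spaces ("optimizable" presets).
SEARCH_SPACES: dict[str, list[Dimension]] = {
    "svm": [
        Real("C", 1e-3, 1e3, log=True),
        Real("kernel_scale", 1e-3, 1e3, log=True),
        Categorical("kernel", ("linear", "quadratic", "cubic", "rbf")),
    ],
    "knn": [
        Integer("n_neighbors", 1, 30),
        Categorical("metric", ("euclidean", "cityblock", "cosine")),
        Categorical("weights", ("uniform", "distance")),
    ],
    "decision_tree": [
        Integer("max_depth", 1, 30),
        Integer("min_samples_leaf", 1, 50),
    ],
    "ensemble": [
        Categorical("method", ("bagging", "adaboost", "random_subspace")),
        Integer("n_estimators", 10, 300, log=True),
        Real("learning_rate", 0.01, 1.0, log=True),
    ],
    "mlp": [
        Integer("n_layers", 1, 3),
        Integer("width", 5, 300, log=True),
        Real("alpha", 1e-6, 1e-1, log=True),
    ],
    "lda": [Real("shrinkage", 0.0, 1.0)],
    "logistic": [Real("C", 1e-3, 1e3, log=True)],
    "naive_bayes": [Real("var_smoothing", 1e-12, 1e-3, log=True)],
}


def _estimator_from_params(family: str, params: dict, seed: int,
                           n_features: int) -> BaseEstimator:
    d = max(n_features, 1)
    if family == "svm":
        kernel = params["kernel"]
        gamma = 1.0 / params["kernel_scale"] ** 2
        degree = {"quadratic": 2, "cubic": 3}.get(kernel, 3)
        skl_kernel = {"linear": "linear", "quadratic": "poly",
                      "cubic": "poly", "rbf": "rbf"}[kernel]
        return SVC(kernel=skl_kernel, degree=degree, C=params["C"],
                   gamma=gamma, coef0=1.0, random_state=seed)
    if family == "knn":
        metric = {"euclidean": "euclidean", "cityblock": "manhattan",
                  "cosine": "cosine"}[params["metric"]]
        return KNeighborsClassifier(n_neighbors=params["n_neighbors"],
                                    metric=metric, weights=params["weights"])
    if family == "decision_tree":
        return DecisionTreeClassifier(max_depth=params["max_depth"],
                                      min_samples_leaf=params["min_samples_leaf"],
                                      random_state=seed)
    if family == "ensemble":
        method = params["method"]
        n_est = params["n_estimators"]
        if method == "bagging":
            return BaggingClassifier(DecisionTreeClassifier(random_state=seed),
                                     n_estimators=n_est, random_state=seed)
        if method == "adaboost":
            return AdaBoostClassifier(
                DecisionTreeClassifier(max_depth=1, random_state=seed),
                n_estimators=n_est, learning_rate=params["learning_rate"],
                random_state=seed)
        return BaggingClassifier(KNeighborsClassifier(n_neighbors=5),
                                 n_estimators=n_est, max_features=0.5,
                                 bootstrap=False, random_state=seed)
    if family == "mlp":
        layers = tuple([params["width"]] * params["n_layers"])
        return MLPClassifier(layers, alpha=params["alpha"], max_iter=800,
                             random_state=seed)
    if family == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr",
                                          shrinkage=params["shrinkage"])
    if family == "logistic":
        return LogisticRegression(C=params["C"], max_iter=2000,
                                  random_state=seed)
    if family == "naive_bayes":
        return GaussianNB(var_smoothing=params["var_smoothing"])
    raise ValueError(f"unknown family {family!r}")


def estimator_from_params(family: str, params: dict, seed: int = 0,
                          n_features: int = 1) -> BaseEstimator:
    """Concrete sklearn estimator for a point of a family's search space
    (e.g. the ``best_params_`` of a finished optimization)."""
    return _estimator_from_params(family, params, seed, n_features)


def _cv_loss(est: BaseEstimator, X: np.ndarray, y: np.ndarray,
             n_folds: int, seed: int) -> float:
    """Mean misclassification over stratified folds, z-scored per fold."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        pipe = Pipeline([("scale", StandardScaler()), ("clf", clone(est))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipe.fit(X[tr], y[tr])
        errs.append(float(np.mean(pipe.predict(X[te]) != y[te])))
    return float(np.mean(errs))


def bayes_optimize(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    cfg: OptimizationConfig = OptimizationConfig(),
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Tune ``family``'s hyperparameters to minimize CV misclassification.

    Returns (best_params, best_cv_loss, trace); the trace records every
    (params, loss) evaluation, suitable for minimum-classification-error plots.
    """
    if family not in SEARCH_SPACES:
        raise ValueError(f"no search space for family {family!r}")
    X, y = _check_xy(X, y)

    def objective(params: dict) -> float:
        est = _estimator_from_params(family, params, cfg.seed, X.shape[1])
        return _cv_loss(est, X, y, cfg.n_folds, cfg.seed)

    return gp_minimize(objective, SEARCH_SPACES[family],
                       n_iterations=cfg.n_iterations, seed=cfg.seed,
                       n_initial=cfg.n_initial, xi=cfg.xi)


class BayesSearchClassifier(ClassifierMixin, BaseEstimator):
    """Bayesian-optimized classifier of one family (sklearn estimator API).

    ``fit`` tunes the family's hyperparameters by GP/EI search over the
    registry search space (objective: stratified CV misclassification with
    fold-internal normalization), then refits the best configuration on the
    full training set behind a z-scoring pipeline.

    Attributes (after fit)
    ----------------------
    best_params_ : dict of tuned hyperparameters.
    best_loss_ : CV misclassification of the best configuration.
    trace_ : list of (params, loss) per optimization iteration.
    best_estimator_ : fitted Pipeline(scaler, classifier).
    """

    def __init__(self, family: str = "knn", n_iterations: int = 30,
                 n_folds: int = 10, n_initial: int = 5, xi: float = 0.01,
                 seed: int = 0):
        self.family = family
        self.n_iterations = n_iterations
        self.n_folds = n_folds
        self.n_initial = n_initial
        self.xi = xi
        self.seed = seed

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        cfg = OptimizationConfig(n_iterations=self.n_iterations,
                                 n_folds=self.n_folds,
                                 n_initial=self.n_initial, xi=self.xi,
                                 seed=self.seed)
        best, loss, trace = bayes_optimize(self.family, X, y, cfg)
        self.best_params_ = best
        self.best_loss_ = loss
        self.trace_ = trace
        est = _estimator_from_params(self.family, best, self.seed, X.shape[1])
        self.best_estimator_ = Pipeline(
            [("scale", StandardScaler()), ("clf", est)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.best_estimator_.fit(X, y)
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return self.best_estimator_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return decision_scores(self.best_estimator_, np.asarray(X, dtype=float))
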