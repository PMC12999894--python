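"""Evaluation protocols: segment-level k-fold CV, subject-wise LOOCV,
lobe-wise sweeps, and paired comparison statistics.

Subject-wise LOOCV holds out every segment of one subject per fold, so no
within-subject information leaks from training to test; the reported mean is
the unweighted mean of per-subject segment accuracies (not segment-pooled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .dataset import FeatureTable, apply_normalizer, fit_normalizer, subset_lobe
from .io_eeg import LOBES, MontageMap
from .models import (
    ClassifierSpec,
    EvaluationReport,
    decision_scores,
    report_from_confusion,
    train,
)

__all__ = [
    "LOOCVReport",
    "PairedComparison",
    "kfold_cv",
    "subject_loocv",
    "paired_subject_cv",
    "lobewise_sweep",
    "paired_comparison",
]


@dataclass
class LOOCVReport:
    """Per-subject segment accuracies (%) with their mean and sample SD."""

    per_subject_accuracy: dict
    mean_accuracy: float
    sd_accuracy: float

    @classmethod
    def from_per_subject(cls, per_subject: dict) -> "LOOCVReport":
        vals = np.asarray(list(per_subject.values()), dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError("per-subject accuracies must lie in [0, 100]")
        return cls(
            per_subject_accuracy=dict(per_subject),
            mean_accuracy=float(vals.mean()),
            sd_accuracy=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        )


@dataclass
class PairedComparison:
    """Two-sided paired t-test on differences b - a, with paired Cohen's d."""

    n: int
    mean_diff: float
    t_stat: float
    p_value: float
    cohens_d: float


def _fit_fold(spec, X_tr, y_tr, X_te, seed: int):
    """Normalize on the training rows only, fit, and score the test rows.

    ``spec`` is either a registry ClassifierSpec or a ready sklearn estimator
    (e.g. the best configuration found by Bayesian optimization), which is
    cloned per fold.
    """
    norm = fit_normalizer(X_tr)
    if isinstance(spec, ClassifierSpec):
        model = train(spec, apply_normalizer(norm, X_tr), y_tr, seed=seed)
    else:
        from sklearn.base import clone

        model = clone(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(apply_normalizer(norm, X_tr), y_tr)
    Xs = apply_normalizer(norm, X_te)
    return model, model.predict(Xs).astype(int), decision_scores(model, Xs)


def kfold_cv(
    spec: ClassifierSpec,
    tab: FeatureTable,
    k: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified segment-level k-fold CV with fold-internal normalization;
    confusion counts pooled across folds."""
    counts = np.bincount(tab.y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds minority class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tn = fp = fn = tp = 0
    all_scores = np.empty(tab.n_segments)
    fold_acc = []
    for tr, te in skf.split(tab.X, tab.y):
        _, pred, scores = _fit_fold(spec, tab.X[tr], tab.y[tr], tab.X[te], seed)
        yt = tab.y[te]
        tp += int(np.sum((pred == 1) & (yt == 1)))
        tn += int(np.sum((pred == 0) & (yt == 0)))
        fp += int(np.sum((pred == 1) & (yt == 0)))
        fn += int(np.sum((pred == 0) & (yt == 1)))
        all_scores[te] = scores
        fold_acc.append(100.0 * float(np.mean(pred == yt)))
    return report_from_confusion(tn, fp, fn, tp, all_scores, tab.y,
                                 per_fold_accuracy=fold_acc)


def subject_loocv(spec: ClassifierSpec, tab: FeatureTable, seed: int = 0) -> LOOCVReport:
    """Leave-one-subject-out: train on all other subjects' segments
    (normalizer fit on train only), test on the held-out subject."""
    subjects = list(dict.fromkeys(tab.subject_ids.tolist()))  # stable order
    if len(subjects) < 3:
        raise ValueError("subject-wise LOOCV needs >= 3 subjects")
    per_subject = {}
    for sid in subjects:
        te = tab.subject_ids == sid
        tr = ~te
        if not te.any():
            raise ValueError(f"subject {sid} has zero segments")
        assert not np.any(te & tr), "train/test subject overlap"
        if len(np.unique(tab.y[tr])) < 2:
            raise ValueError(f"training fold for subject {sid} lost a class")
        _, pred, _ = _fit_fold(spec, tab.X[tr], tab.y[tr], tab.X[te], seed)
        per_subject[sid] = 100.0 * float(np.mean(pred == tab.y[te]))
    return LOOCVReport.from_per_subject(per_subject)


def paired_subject_cv(spec: ClassifierSpec, tab: FeatureTable,
                      seed: int = 0) -> float:
    """Leave-one-subject-per-class-out pooled accuracy (%).

    Each fold holds out one patient and one control subject, keeping the
    training classes balanced; like subject-wise LOOCV this protocol is free
    of within-subject leakage, and unlike it the held-out fold never skews
    the training class ratio (which biases near-chance problems below
    chance).  Used for null-contrast calibration experiments.
    """
    subjects = list(dict.fromkeys(tab.subject_ids.tolist()))
    by_class = {0: [], 1: []}
    for sid in subjects:
        by_class[int(tab.y[tab.subject_ids == sid][0])].append(sid)
    if not by_class[0] or not by_class[1]:
        raise ValueError("both classes must be represented")
    n_folds = min(len(by_class[0]), len(by_class[1]))
    correct = total = 0
    for i in range(n_folds):
        held = {by_class[0][i], by_class[1][i]}
        te = np.isin(tab.subject_ids, list(held))
        tr = ~te
        _, pred, _ = _fit_fold(spec, tab.X[tr], tab.y[tr], tab.X[te], seed)
        correct += int(np.sum(pred == tab.y[te]))
        total += int(te.sum())
    return 100.0 * correct / total


def lobewise_sweep(
    specs: list[ClassifierSpec],
    tab: FeatureTable,
    montage: MontageMap,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[tuple[str, ClassifierSpec, EvaluationReport]], dict]:
    """Evaluate every spec on every lobe subset with identical folds.

    Returns (rows, best_per_lobe) where rows holds one (lobe, spec, report)
    per combination and best_per_lobe maps lobe -> (spec, report) chosen by
    accuracy (first spec in list order wins ties).
    """
    rows = []
    best: dict = {}
    for lobe in LOBES:
        sub = subset_lobe(tab, montage, lobe)
        for spec in specs:
            rep = kfold_cv(spec, sub, k=k, seed=seed)
            rows.append((lobe, spec, rep))
            if lobe not in best or rep.accuracy > best[lobe][1].accuracy:
                best[lobe] = (spec, rep)
    return rows, best


def paired_comparison(a, b) -> PairedComparison:
    """Two-sided paired t-test of b against a (differences d = b - a).

    t = mean(d) / (sd(d)/sqrt(n)); Cohen's d (paired) = mean(d)/sd(d).
    Zero-variance differences give NaN t/p (sentinel) with a warning, except
    the all-zero case where t=0, p=1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    d = b - a
    n = d.size
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(n, 0.0, 0.0, 1.0, 0.0)
        warnings.warn("zero-variance nonzero differences: t/p undefined",
                      UserWarning, stacklevel=2)
        return PairedComparison(n, mean, float("nan"), float("nan"),
                                float("nan"))
    res = stats.ttest_rel(b, a)
    return PairedComparison(
        n=n,
        mean_diff=mean,
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=mean / sd,
    )
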