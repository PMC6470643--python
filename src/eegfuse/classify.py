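"""Gaussian-kernel SVM evaluation with nested grid search and LOOCV.

Each subject is classified by an RBF-kernel SVM trained on all other
subjects (leave-one-out). Within every outer fold, C and gamma are tuned
by a 3-stage coarse-to-fine grid search over exponentially growing
sequences 2^-5 .. 2^15, scored by stratified k-fold accuracy on the
training subjects only — the left-out subject never influences the
hyperparameter choice. Features are z-scored with training-fold
statistics inside every fit.

Decision scores pooled across outer folds form a single ROC curve; the
AUC is the Mann-Whitney statistic (ties counting 1/2) of the scores, and
the confusion matrix at decision threshold 0 yields sensitivity
TP/(TP+FN), specificity TN/(FP+TN) and accuracy (TP+TN)/total, with
class 1 as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn import config_context as sklearn_config
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierReport",
    "EvalConfig",
    "compare_feature_sets",
    "confusion_metrics",
    "evaluate_loocv",
    "roc_auc",
]


@dataclass(frozen=True)
class EvalConfig:
    """Nested-CV evaluation settings.

    ``exp_range`` bounds the base-2 exponents searched for both C and
    gamma; ``n_stages`` coarse-to-fine rounds start at step
    ``initial_step`` and halve it each round. Inner model selection uses
    stratified ``inner_folds``-fold accuracy; ``seed`` fixes the inner
    fold shuffling (the outer loop, LOO, is deterministic).
    """

    exp_range: tuple[float, float] = (-5.0, 15.0)
    n_stages: int = 3
    initial_step: float = 4.0
    inner_folds: int = 3
    seed: int = 0
    class_weight: str | None = None

    def __post_init__(self) -> None:
        if self.exp_range[0] >= self.exp_range[1]:
            raise ValueError(f"empty exponent range {self.exp_range}")
        if self.n_stages < 1 or self.inner_folds < 2:
            raise ValueError("need n_stages >= 1 and inner_folds >= 2")


@dataclass
class ClassifierReport:
    """Pooled LOOCV evaluation of one feature set."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    scores: np.ndarray
    predictions: np.ndarray
    chosen_params: list[dict] = field(default_factory=list)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(FP+TN), accuracy (TP+TN)/all."""
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (fp + tn) if fp + tn else float("nan")
    acc = (tp + tn) / (tp + fn + fp + tn)
    return sens, spec, acc


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC of decision scores for binary labels.

    AUC is computed as the normalised Mann-Whitney statistic via mid
    ranks, so tied scores contribute 1/2. Returns (fpr, tpr, auc).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute a ROC")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return fpr, tpr, float(auc)


def _candidate_exponents(center: float, step: float, lo: float, hi: float) -> np.ndarray:
    exps = center + step * np.arange(-1, 2)
    return np.unique(np.clip(exps, lo, hi))


def _make_svm(C: float, gamma: float, cfg: EvalConfig):
    return make_pipeline(
        StandardScaler(),
        SVC(C=C, gamma=gamma, kernel="rbf", class_weight=cfg.class_weight),
    )


def select_hyperparams(
    X: np.ndarray, y: np.ndarray, cfg: EvalConfig
) -> tuple[float, float]:
    """3-stage coarse-to-fine grid search for (C, gamma) by inner-CV accuracy.

    Stage 1 scans the full exponent range with step ``initial_step``;
    each later stage scans +/- 2 steps around the previous optimum with
    the step halved. Ties resolve to the first candidate in scan order
    (smallest C, then smallest gamma), making selection deterministic.
    Features are z-scored per inner fold with training statistics only.
    """
    lo, hi = cfg.exp_range
    n_splits = min(cfg.inner_folds, int(np.bincount(y).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
    folds = []
    for tr, te in skf.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        folds.append(((X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd, y[te]))
    n = X.shape[0]
    cache: dict[tuple[float, float], float] = {}

    def score(ce: float, ge: float) -> float:
        key = (ce, ge)
        if key not in cache:
            correct = 0
            for Xtr, ytr, Xte, yte in folds:
                clf = SVC(C=2.0**ce, gamma=2.0**ge, kernel="rbf", class_weight=cfg.class_weight)
                clf.fit(Xtr, ytr)
                correct += int((clf.predict(Xte) == yte).sum())
            cache[key] = correct / n
        return cache[key]

    step = cfg.initial_step
    c_exps = np.arange(lo, hi + 1e-9, step)
    g_exps = np.arange(lo, hi + 1e-9, step)
    best_c, best_g = c_exps[0], g_exps[0]
    with sklearn_config(assume_finite=True):  # inputs validated by the caller
        for stage in range(cfg.n_stages):
            if stage > 0:
                step /= 2.0
                c_exps = _candidate_exponents(best_c, step, lo, hi)
                g_exps = _candidate_exponents(best_g, step, lo, hi)
            best_score = -np.inf
            for ce in c_exps:
                for ge in g_exps:
                    s = score(ce, ge)
                    if s > best_score + 1e-12:
                        best_score, best_c, best_g = s, ce, ge
    return 2.0**best_c, 2.0**best_g


def evaluate_loocv(
    features: np.ndarray, labels: np.ndarray, cfg: EvalConfig = EvalConfig()
) -> ClassifierReport:
    """Leave-one-out evaluation of an RBF SVM with per-fold nested tuning.

    For each left-out subject, (C, gamma) are selected on the remaining
    subjects only, a fresh model is fitted on them, and the held-out
    decision score and prediction are recorded. Scores pooled over folds
    give the ROC/AUC; the confusion matrix uses threshold 0.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_subjects, n_features) matching labels")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError(f"need >= 2 subjects per class, got counts {counts.tolist()}")

    n = X.shape[0]
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    chosen: list[dict] = []
    for i in range(n):
        tr = np.setdiff1d(np.arange(n), [i])
        C, gamma = select_hyperparams(X[tr], y[tr], cfg)
        clf = _make_svm(C, gamma, cfg)
        clf.fit(X[tr], y[tr])
        scores[i] = float(clf.decision_function(X[i : i + 1])[0])
        preds[i] = int(clf.predict(X[i : i + 1])[0])
        chosen.append({"C": C, "gamma": gamma})

    tp = int(((preds == 1) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    sens, spec, acc = confusion_metrics(tp, fn, tn, fp)
    _, _, auc = roc_auc(scores, y)
    return ClassifierReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        scores=scores,
        predictions=preds,
        chosen_params=chosen,
    )


def compare_feature_sets(
    sets: dict[str, np.ndarray],
    labels: np.ndarray,
    cfg: EvalConfig = EvalConfig(),
) -> tuple[pd.DataFrame, dict[str, ClassifierReport]]:
    """Evaluate several feature sets under identical CV conditions.

    The outer LOO partition is deterministic and the same config (hence
    the same inner-fold seed) is used for every set, so differences in
    the summary table reflect the features alone. Returns a summary
    DataFrame (accuracy, sensitivity, specificity, AUC per set) plus the
    full reports.
    """
    labels = np.asarray(labels).astype(int).ravel()
    reports: dict[str, ClassifierReport] = {}
    rows = []
    for name, mat in sets.items():
        rep = evaluate_loocv(mat, labels, cfg)
        reports[name] = rep
        rows.append(
            {
                "set": name,
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "auc": rep.auc,
            }
        )
    return pd.DataFrame(rows).set_index("set"), reports
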