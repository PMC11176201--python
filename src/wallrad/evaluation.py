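"""Repeated stratified K-fold evaluation of feature subsets.

The default classifier is a linear maximum-margin model (soft-margin SVM,
unit cost) preceded by per-fold z-scaling fitted on the training rows
only.  Metrics are computed from the validation predictions pooled within
a repeat: accuracy, sensitivity (recall of the positive, IPSS >= 8,
class), specificity, balanced accuracy, and the trapezoidal ROC AUC with
midrank tie handling.  Averages over repeats stabilize the estimates; the
full procedure is a pure function of (inputs, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import FeatureTable, WallRadError


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: per-class round-robin after a seeded shuffle.

    Within each class the fold sizes differ by at most one, so every fold
    preserves the class distribution as closely as integer counts allow.
    """
    labels = np.asarray(labels).astype(int)
    if k < 2:
        raise WallRadError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(labels.size, -1, dtype=int)
    if k == labels.size:  # leave-one-out degenerate case: singleton folds
        folds[rng.permutation(labels.size)] = np.arange(labels.size)
        return folds
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise WallRadError(f"class {cls} has {idx.size} cases, fewer than k={k}")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def train_classifier(
    X: np.ndarray, y: np.ndarray, spec: str = "linear_svm"
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit the configured classifier; returns a scoring function.

    The score is a signed decision value with the class rule score > 0 →
    positive.  Features are z-scaled with statistics from the given rows
    only (constant features are left unscaled by the scaler's variance
    guard).
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise WallRadError("training labels contain a single class")
    if spec == "linear_svm":
        model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        model.fit(X, y)
        return model.decision_function
    if spec == "logistic":
        model = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
        model.fit(X, y)
        return model.decision_function
    if spec == "random_forest":
        model = make_pipeline(
            StandardScaler(), RandomForestClassifier(n_estimators=200, random_state=0)
        )
        model.fit(X, y)
        return lambda Z: model.predict_proba(Z)[:, 1] - 0.5
    raise WallRadError(f"unknown classifier spec {spec!r}")


def roc_points(truth: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve (fpr, tpr, thresholds) sweeping unique score thresholds.

    Tied scores collapse into a single threshold step, which makes the
    trapezoidal area equal to the midrank (pair-counting with half credit
    for ties) statistic.
    """
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    s, t = scores[order], truth[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(t)[distinct]
    fp = np.cumsum(1 - t)[distinct]
    P, N = t.sum(), (1 - t).sum()
    tpr = np.r_[0.0, tp / P]
    fpr = np.r_[0.0, fp / N]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def auc_trapezoid(truth: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC by the trapezoidal rule."""
    fpr, tpr, _ = roc_points(truth, scores)
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(
    truth: np.ndarray, scores: np.ndarray, threshold: float = 0.0
) -> dict[str, float]:
    """Binary classification metrics at a score threshold.

    Sensitivity is the recall of the positive class; balanced accuracy is
    the mean of sensitivity and specificity; AUC is threshold-free.
    """
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(truth)) < 2:
        raise WallRadError("metrics require both classes in the truth vector")
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "accuracy": (tp + tn) / truth.size,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
        "auc": auc_trapezoid(truth, scores),
    }


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "balanced_accuracy", "auc")


@dataclass(frozen=True)
class EvaluationReport:
    """CV-averaged metrics with per-repeat traces and pooled ROC points."""

    subset: tuple[str, ...]
    k: int
    repeats: int
    seed: int
    mean: dict[str, float]
    sd: dict[str, float]
    per_repeat: dict[str, list[float]]
    roc_fpr: list[float]
    roc_tpr: list[float]

    def to_json(self, path: Optional[Path | str] = None) -> str:
        payload = {
            "subset": list(self.subset),
            "fold_scheme": {"k": self.k, "repeats": self.repeats, "seed": self.seed},
            "mean": self.mean,
            "sd": self.sd,
            "per_repeat": self.per_repeat,
            "roc": {"fpr": self.roc_fpr, "tpr": self.roc_tpr},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _cv_scores_once(
    X: np.ndarray, y: np.ndarray, k: int, seed: int, classifier: str
) -> np.ndarray:
    """Pooled out-of-fold decision scores for one CV pass."""
    folds = stratified_folds(y, k, seed)
    scores = np.empty(y.size, dtype=float)
    for f in range(k):
        val = folds == f
        fn = train_classifier(X[~val], y[~val], classifier)
        scores[val] = fn(X[val])
    return scores


def repeated_cv(
    table: FeatureTable | np.ndarray,
    labels: np.ndarray,
    subset: Optional[Sequence[str]] = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    classifier: str = "linear_svm",
) -> EvaluationReport:
    """Repeated stratified K-fold CV of one feature subset.

    Each repeat reshuffles the folds with a seed derived from ``seed`` and
    the repeat index, computes metrics from its pooled validation scores,
    and the report averages over repeats.  The first repeats of a longer
    run coincide with a shorter run at the same seed.
    """
    if isinstance(table, FeatureTable):
        names = tuple(subset) if subset is not None else table.feature_names
        X = table.columns(names)
    else:
        X = np.asarray(table, dtype=float)
        names = tuple(subset) if subset is not None else tuple(
            f"x{i}" for i in range(X.shape[1])
        )
    if X.shape[1] == 0:
        raise WallRadError("empty feature subset")
    y = np.asarray(labels).astype(int)

    per_repeat: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    all_truth, all_scores = [], []
    for r in range(repeats):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        scores = _cv_scores_once(X, y, k, rep_seed, classifier)
        m = compute_metrics(y, scores)
        for key in METRIC_NAMES:
            per_repeat[key].append(m[key])
        all_truth.append(y)
        all_scores.append(scores)
    fpr, tpr, _ = roc_points(np.concatenate(all_truth), np.concatenate(all_scores))
    return EvaluationReport(
        subset=names,
        k=k,
        repeats=repeats,
        seed=seed,
        mean={m: float(np.mean(v)) for m, v in per_repeat.items()},
        sd={m: float(np.std(v)) for m, v in per_repeat.items()},
        per_repeat=per_repeat,
        roc_fpr=[float(v) for v in fpr],
        roc_tpr=[float(v) for v in tpr],
    )


def naive_baseline(labels: np.ndarray) -> dict[str, float | bool]:
    """Metrics of the classifier that always predicts the majority class.

    Its accuracy equals the majority class fraction and its balanced
    accuracy is 0.5.  AUC is undefined for a constant score and reported
    as 0.5 with a degenerate flag.
    """
    y = np.asarray(labels).astype(int)
    if y.size == 0:
        raise WallRadError("empty labels")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    majority_positive = n_pos > n_neg
    degenerate = n_pos == 0 or n_neg == 0
    acc = max(n_pos, n_neg) / y.size
    sens = 1.0 if majority_positive else 0.0
    spec = 0.0 if majority_positive else 1.0
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": 0.5 if not degenerate else float("nan"),
        "auc": 0.5,
        "auc_degenerate": True,
        "single_class": degenerate,
    }


def subset_comparison(
    table: FeatureTable,
    labels: np.ndarray,
    subsets: dict[str, Sequence[str]],
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    classifier: str = "linear_svm",
) -> dict[str, EvaluationReport]:
    """Evaluate several named subsets under identical fold seeds.

    Using the same seed for every subset pairs the comparisons: each
    subset sees exactly the same fold splits.
    """
    out: dict[str, EvaluationReport] = {}
    for name, cols in subsets.items():
        if not cols:
            raise WallRadError(f"subset {name!r} is empty")
        out[name] = repeated_cv(
            table, labels, subset=cols, k=k, repeats=repeats, seed=seed, classifier=classifier
        )
    return out
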