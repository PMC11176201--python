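"""Optimal-biomarker-style hybrid feature selection.

Three legs combine into one search: a *filter* leg ranks features by
univariate p-value and keeps a pool of the best; a redundancy pass prunes
the pool of features highly correlated with better-ranked ones; a
*wrapper/embedded* leg then searches subsets of the pool greedily —
forward additions plus member-swap refinements — scoring every candidate
subset by repeated stratified cross-validation of the downstream
classifier, and iterating sweeps until no move improves the objective.
Four literature baselines (MRMR, chi-square, ANOVA, Kruskal-Wallis top-k)
are provided for comparison.

The search is deterministic: all CV splits derive from the configured
seed, and candidate moves are enumerated in a fixed order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.feature_selection import f_classif

from .core import FeatureTable, WallRadError
from .evaluation import repeated_cv
from .univariate_analysis import UnivariateResult, correlation_matrix, univariate_pvalues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    filter_pool_size: int = 200
    redundancy_threshold: float = 0.9
    max_subset_size: int = 10
    wrapper_folds: int = 5
    wrapper_repeats: int = 10
    convergence_patience: int = 2
    objective: str = "accuracy"
    classifier: str = "linear_svm"
    improvement_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.filter_pool_size >= self.max_subset_size >= 1):
            raise WallRadError("need filter_pool_size >= max_subset_size >= 1")
        if not (0 < self.redundancy_threshold <= 1):
            raise WallRadError("redundancy threshold must be in (0, 1]")
        if self.objective not in ("accuracy", "balanced_accuracy"):
            raise WallRadError(f"unknown objective {self.objective!r}")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the subset search."""

    selected: tuple[str, ...]  # ordered by inclusion
    objective_trace: tuple[float, ...]  # objective after each accepted move
    converged: bool
    n_evaluated: int
    pool: tuple[str, ...]


def redundancy_prune(
    ranked_features: Sequence[str],
    feature_names: Sequence[str],
    corr: np.ndarray,
    rho: float,
) -> list[str]:
    """Greedy redundancy pruning in filter-rank order.

    Scanning from the best-ranked feature down, a feature is dropped when
    its absolute Pearson correlation with any already-kept feature
    exceeds ``rho``.  Deterministic given the ranking.
    """
    index = {n: i for i, n in enumerate(feature_names)}
    kept: list[str] = []
    for name in ranked_features:
        i = index[name]
        if all(abs(corr[i, index[k]]) <= rho for k in kept):
            kept.append(name)
    return kept


def _objective(
    table: FeatureTable,
    labels: np.ndarray,
    subset: tuple[str, ...],
    cfg: SelectionConfig,
    cache: dict,
) -> float:
    key = frozenset(subset)
    if key not in cache:
        report = repeated_cv(
            table,
            labels,
            subset=subset,
            k=cfg.wrapper_folds,
            repeats=cfg.wrapper_repeats,
            seed=cfg.seed,
            classifier=cfg.classifier,
        )
        cache[key] = report.mean[cfg.objective]
    return cache[key]


def build_pool(
    table: FeatureTable,
    labels: np.ndarray,
    cfg: SelectionConfig,
    univariate: Optional[UnivariateResult] = None,
) -> list[str]:
    """Filter + redundancy legs: ranked, pruned candidate pool."""
    uni = univariate or univariate_pvalues(table, labels)
    ranked = uni.ranked_features()[: cfg.filter_pool_size]
    corr, _ = correlation_matrix(table)
    return redundancy_prune(ranked, table.feature_names, corr, cfg.redundancy_threshold)


def obm_search(
    table: FeatureTable,
    labels: np.ndarray,
    cfg: Optional[SelectionConfig] = None,
    univariate: Optional[UnivariateResult] = None,
) -> SelectionResult:
    """Greedy forward selection with swap refinement over the pruned pool.

    Starting from the empty subset, each sweep evaluates every single-move
    neighbour: adding any pool feature (while below ``max_subset_size``)
    and, for subsets of two or more, replacing any member with any pool
    feature.  The single best move is accepted if it improves the CV
    objective by more than the tolerance; the search stops after
    ``convergence_patience`` sweeps without an accepted move.
    """
    cfg = cfg or SelectionConfig()
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise WallRadError("labels contain a single class")

    pool = build_pool(table, y, cfg, univariate)
    cache: dict = {}
    selected: list[str] = []
    trace: list[float] = []
    best = -np.inf
    stale = 0
    converged = False

    while True:
        candidates: list[tuple[str, tuple[str, ...]]] = []
        if len(selected) < cfg.max_subset_size:
            for f in pool:
                if f not in selected:
                    candidates.append(("add", tuple(selected) + (f,)))
        if len(selected) >= 2:
            for i in range(len(selected)):
                for f in pool:
                    if f not in selected:
                        swapped = list(selected)
                        swapped[i] = f
                        candidates.append(("swap", tuple(swapped)))
        if not candidates:
            converged = True
            break

        best_move, best_subset, best_score = None, None, best
        for move, subset in candidates:
            score = _objective(table, y, subset, cfg, cache)
            if score > best_score + cfg.improvement_tol:
                best_move, best_subset, best_score = move, subset, score
        if best_move is None:
            stale += 1
            if stale >= cfg.convergence_patience:
                converged = True
                break
            continue
        stale = 0
        selected = list(best_subset)
        best = best_score
        trace.append(best)
        logger.info("accepted %s -> %s (objective %.4f)", best_move, selected, best)

    return SelectionResult(
        selected=tuple(selected),
        objective_trace=tuple(trace),
        converged=converged,
        n_evaluated=len(cache),
        pool=tuple(pool),
    )


# ---------------------------------------------------------------------------
# literature baselines


def baseline_select(
    table: FeatureTable,
    labels: np.ndarray,
    method: str,
    k: int = 10,
) -> list[str]:
    """Top-k features by one of the literature criteria.

    * ``anova`` — one-way F statistic (for two classes identical to the
      squared-t ranking);
    * ``kruskal`` — Kruskal-Wallis H (rank-based, monotone-invariant);
    * ``chi2`` — chi-square score after shifting each feature to be
      nonnegative (subtracting the column minimum);
    * ``mrmr`` — greedy minimum-redundancy maximum-relevance: maximize
      F-statistic relevance minus mean absolute Pearson correlation with
      the already-selected features.
    """
    y = np.asarray(labels).astype(int)
    X = table.values
    names = list(table.feature_names)
    k = min(k, len(names))

    if method == "anova":
        F, _ = f_classif(X, y)
        F = np.nan_to_num(F, nan=-np.inf)
        order = np.argsort(-F, kind="mergesort")
        return [names[i] for i in order[:k]]

    if method == "kruskal":
        scores = np.full(len(names), -np.inf)
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.ptp(col) == 0:
                continue
            scores[j] = stats.kruskal(col[y == 0], col[y == 1]).statistic
        order = np.argsort(-scores, kind="mergesort")
        return [names[i] for i in order[:k]]

    if method == "chi2":
        shifted = X - X.min(axis=0, keepdims=True)
        scores, _ = sk_chi2(shifted, y)
        scores = np.nan_to_num(scores, nan=-np.inf)
        order = np.argsort(-scores, kind="mergesort")
        return [names[i] for i in order[:k]]

    if method == "mrmr":
        F, _ = f_classif(X, y)
        relevance = np.nan_to_num(F, nan=0.0)
        sd = X.std(axis=0)
        Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        R = np.abs(np.corrcoef(Z, rowvar=False))
        R = np.nan_to_num(np.atleast_2d(R), nan=0.0)
        chosen: list[int] = [int(np.argmax(relevance))]
        while len(chosen) < k:
            best_j, best_score = None, -np.inf
            for j in range(len(names)):
                if j in chosen:
                    continue
                score = relevance[j] - R[j, chosen].mean()
                if score > best_score:
                    best_j, best_score = j, score
            chosen.append(best_j)
        return [names[j] for j in chosen]

    raise WallRadError(f"unknown selection method {method!r}")
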