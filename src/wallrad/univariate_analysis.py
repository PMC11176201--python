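"""Per-feature class discrimination statistics and feature correlation.

Each feature gets a Welch unequal-variance two-sample test of the mean
difference between the negative (IPSS < 8) and positive (IPSS >= 8)
groups; features are ranked ascending by p-value.  These p-values are a
ranking device for the filter stage of feature selection, not formal
inference, so no multiple-testing correction enters the ranking —
Benjamini-Hochberg q-values are reported alongside for information only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureTable, WallRadError


@dataclass(frozen=True)
class UnivariateResult:
    """Per-feature group statistics, ranked ascending by p-value.

    ``table`` columns: feature, category, mean_negative, mean_positive,
    sd_negative, sd_positive, t, p_value, q_value, rank.  Degenerate
    features (zero variance in both groups with equal means undefined)
    carry a NaN p-value and rank last.
    """

    table: pd.DataFrame

    def ranked_features(self) -> list[str]:
        return self.table["feature"].tolist()

    def pvalues(self) -> np.ndarray:
        return self.table.set_index("feature")["p_value"].to_numpy()


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN passes through."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def univariate_pvalues(table: FeatureTable, labels: np.ndarray) -> UnivariateResult:
    """Welch t-test of each feature between the two classes.

    Ranking is ascending by p; ties break by descending absolute
    standardized mean difference, then by name.  A feature with zero
    variance in both groups gets a sentinel NaN p (or p = 1 when the two
    group samples are literally equal in mean, which Welch handles as
    t = 0).
    """
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise WallRadError("labels must be binary 0/1")
    n_neg, n_pos = int((labels == 0).sum()), int((labels == 1).sum())
    if n_neg < 2 or n_pos < 2:
        raise WallRadError("need at least 2 cases per class")
    X = table.values
    neg, pos = X[labels == 0], X[labels == 1]
    mean_n, mean_p = neg.mean(axis=0), pos.mean(axis=0)
    sd_n, sd_p = neg.std(axis=0, ddof=1), pos.std(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(pos, neg, equal_var=False, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    both_const = (sd_n < 1e-300) & (sd_p < 1e-300)
    equal_means = np.isclose(mean_n, mean_p)
    # identical samples in both groups: no evidence of difference
    p[both_const & equal_means] = 1.0
    t[both_const & equal_means] = 0.0
    p[both_const & ~equal_means] = np.nan  # degenerate sentinel

    pooled = np.sqrt((sd_n**2 + sd_p**2) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = np.where(pooled > 0, (mean_p - mean_n) / np.where(pooled > 0, pooled, 1.0), 0.0)

    df = pd.DataFrame(
        {
            "feature": list(table.feature_names),
            "category": [d.category for d in table.descriptors],
            "mean_negative": mean_n,
            "mean_positive": mean_p,
            "sd_negative": sd_n,
            "sd_positive": sd_p,
            "t": t,
            "p_value": p,
            "q_value": _bh_qvalues(p),
            "abs_smd": np.abs(smd),
        }
    )
    df["_p_sort"] = df["p_value"].fillna(np.inf)
    df = df.sort_values(
        by=["_p_sort", "abs_smd", "feature"], ascending=[True, False, True]
    ).drop(columns=["_p_sort"])
    df["rank"] = np.arange(1, len(df) + 1)
    return UnivariateResult(table=df.reset_index(drop=True))


def top_k_by_category(result: UnivariateResult, category: str, k: int) -> pd.DataFrame:
    """The k smallest-p features restricted to one category.

    If the category has fewer than k features, all are returned.
    """
    if k < 1:
        raise WallRadError("k must be >= 1")
    sub = result.table[result.table["category"] == category]
    return sub.head(k).reset_index(drop=True)


def correlation_matrix(table: FeatureTable) -> tuple[np.ndarray, list[str]]:
    """Pearson feature-feature correlation with degenerate-column handling.

    Zero-variance columns get 0 off-diagonal (and are returned as flags);
    the diagonal is exactly 1 and the matrix is symmetric.
    """
    if table.n_cases < 3:
        raise WallRadError("need at least 3 cases for correlations")
    X = table.values
    sd = X.std(axis=0)
    degenerate = sd < 1e-12
    Xs = X.copy()
    Xs[:, degenerate] = 0.0  # avoid 0/0 in corrcoef
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(Xs, rowvar=False)
    R = np.atleast_2d(R)
    R[np.isnan(R)] = 0.0
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    flags = [n for n, d in zip(table.feature_names, degenerate) if d]
    return R, flags


def export_heatmap(R: np.ndarray, path: Path | str) -> None:
    """Correlation heat map as PNG (blue positive, red negative)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(R, cmap="RdBu", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xlabel("feature index")
    ax.set_ylabel("feature index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
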