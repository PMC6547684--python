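"""Wilcoxon rank-sum feature ranking and top-k selection.

Each feature column is scored with a two-sided two-sample Wilcoxon
rank-sum (Mann-Whitney U) test between the positive and negative class.
Features are ranked by ascending p-value; ties are broken by larger
absolute rank-biserial effect and then lexicographic feature name so the
ranking is fully deterministic.  The selected matrix keeps columns in
rank order (most significant first).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["WilcoxonSelector", "rank_features", "select_top_k"]


def _rank_sum_pvalues(
    x_pos: np.ndarray, x_neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column U statistics and two-sided p-values.

    Uses exact null enumeration when both classes have <= 20 samples and
    the column has no cross-class ties; otherwise the normal
    approximation with continuity correction.  Constant columns get
    p = 1 (they carry no ranking information).
    """
    n1, n2 = len(x_pos), len(x_neg)
    n_feat = x_pos.shape[1]
    u_stats = np.empty(n_feat)
    p_values = np.empty(n_feat)
    small = max(n1, n2) <= 20
    for j in range(n_feat):
        a, b = x_pos[:, j], x_neg[:, j]
        if np.ptp(np.concatenate([a, b])) == 0.0:
            u_stats[j] = n1 * n2 / 2.0
            p_values[j] = 1.0
            continue
        has_ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=True
        )
        u_stats[j] = res.statistic
        p_values[j] = min(float(res.pvalue), 1.0)
    return u_stats, p_values


def _rank_sum_pvalues_fast(
    x_pos: np.ndarray, x_neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized asymptotic path for wide matrices (identical formulas)."""
    res = stats.mannwhitneyu(
        x_pos, x_neg, alternative="two-sided", method="asymptotic",
        use_continuity=True, axis=0,
    )
    u = np.asarray(res.statistic, dtype=float)
    p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    const = np.ptp(np.vstack([x_pos, x_neg]), axis=0) == 0.0
    p[const] = 1.0
    u[const] = x_pos.shape[0] * x_neg.shape[0] / 2.0
    return u, p


class WilcoxonSelector(TransformerMixin, BaseEstimator):
    """Rank features by a two-sample Wilcoxon rank-sum test; keep the top k.

    Parameters
    ----------
    k : int or None
        Number of features to retain.  ``None`` keeps all features
        (ranking only).

    Attributes
    ----------
    statistic_ : ndarray
        Mann-Whitney U statistic per feature (positive class first).
    p_values_ : ndarray
        Two-sided p-values per feature.
    effect_ : ndarray
        Rank-biserial effect size ``2*U/(n1*n2) - 1`` per feature;
        positive when the feature is larger in the positive class.
    ranking_ : ndarray
        Column indices ordered from most to least significant.
    selected_indices_ : ndarray
        The first ``k`` entries of ``ranking_``.
    """

    def __init__(self, k: int | None = None):
        self.k = k

    def fit(self, X, y):
        names = list(X.columns) if hasattr(X, "columns") else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {classes}")
        pos, neg = X[y == 1], X[y != 1]
        if min(len(pos), len(neg)) < 2:
            raise ValueError("need at least 2 samples per class")
        if self.k is not None and not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k={self.k} out of range 1..{X.shape[1]}")
        if max(len(pos), len(neg)) <= 20:
            self.statistic_, self.p_values_ = _rank_sum_pvalues(pos, neg)
        else:
            self.statistic_, self.p_values_ = _rank_sum_pvalues_fast(pos, neg)
        self.effect_ = 2.0 * self.statistic_ / (len(pos) * len(neg)) - 1.0
        self.feature_names_in_ = (
            np.asarray([str(c) for c in names], dtype=object)
            if names is not None
            else np.asarray([f"f{i}" for i in range(X.shape[1])], dtype=object)
        )
        order = sorted(
            range(X.shape[1]),
            key=lambda j: (
                self.p_values_[j],
                -abs(self.effect_[j]),
                self.feature_names_in_[j],
            ),
        )
        self.ranking_ = np.asarray(order)
        k = self.k if self.k is not None else X.shape[1]
        self.selected_indices_ = self.ranking_[:k]
        return self

    def fit_transform(self, X, y=None, **fit_params):
        # TransformerMixin would pass y positionally; keep it mandatory here
        return self.fit(X, y).transform(X)

    def transform(self, X):
        arr = np.asarray(X, dtype=float)
        return arr[:, self.selected_indices_]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return self.feature_names_in_[self.selected_indices_]

    def ranked_table(self) -> pd.DataFrame:
        """RankedFeatureList as a DataFrame, most significant first."""
        idx = self.ranking_
        direction = np.where(self.effect_[idx] > 0, "up", "down")
        direction[self.effect_[idx] == 0] = "none"
        return pd.DataFrame(
            {
                "feature": self.feature_names_in_[idx],
                "U": self.statistic_[idx],
                "p_value": self.p_values_[idx],
                "direction": direction,
            }
        )


def rank_features(matrix: pd.DataFrame, labels: Sequence[int]) -> pd.DataFrame:
    """Rank every feature column of ``matrix`` by class-discriminative p-value."""
    return WilcoxonSelector().fit(matrix, np.asarray(labels)).ranked_table()


def select_top_k(ranked: pd.DataFrame, k: int) -> list[str]:
    """First ``k`` feature names of a ranked table, in rank order."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k={k} out of range 1..{len(ranked)}")
    return list(ranked["feature"].iloc[:k])


def write_ranked_table(ranked: pd.DataFrame, path) -> None:
    ranked.to_csv(path, sep="\t", index=False)
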