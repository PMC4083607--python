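"""Discriminative feature ranking and incremental feature selection (IFS).

Features are ranked by a per-feature Fisher discriminant ratio
(μ₊ − μ₋)² / (σ₊² + σ₋²) — the class-difference score the selector family
optimizes in its simplest (linear) form; the scorer is pluggable. IFS then
grows prefixes of the ranked list, evaluates a predictor on each prefix,
and keeps the best-scoring (smallest on ties) prefix as the optimal
feature subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "fisher_score",
    "FisherScoreSelector",
    "IfsResult",
    "incremental_feature_selection",
]


def fisher_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature Fisher discriminant ratio (μ₊ − μ₋)² / (σ₊² + σ₋²).

    Variances are population variances (ddof 0). A feature constant within
    both classes scores 0 when the class means agree and +inf otherwise.
    Requires exactly two classes with ≥ 2 samples each.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"fisher_score needs exactly 2 classes, got {classes.size}")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("fisher_score needs >= 2 samples per class")
    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    den = a.var(axis=0) + b.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / den
    score[(num == 0) & (den == 0)] = 0.0
    score[(num > 0) & (den == 0)] = np.inf
    return score


class FisherScoreSelector(SelectorMixin, BaseEstimator):
    """Rank features by a class-separation score and keep the top ``k``.

    Parameters
    ----------
    k : int or None
        Number of top-ranked features ``transform`` keeps; ``None`` keeps all
        (the selector is then used purely for its ranking).
    scorer : callable, optional
        ``scorer(X, y) -> per-feature score array``; defaults to
        :func:`fisher_score`.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Per-feature scores.
    ranking_ : ndarray of shape (n_features,)
        Feature indices ordered best first; ties broken by lower original
        index. Invariant to sample-order permutation.
    """

    def __init__(
        self,
        k: int | None = None,
        scorer: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    ):
        self.k = k
        self.scorer = scorer

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        scorer = self.scorer or fisher_score
        self.scores_ = np.asarray(scorer(X, y), dtype=float)
        if self.scores_.shape != (X.shape[1],):
            raise ValueError("scorer must return one score per feature")
        # stable sort on -score keeps lower original index first on ties
        self.ranking_ = np.argsort(-self.scores_, kind="stable")
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        k = self.n_features_in_ if self.k is None else self.k
        if not 1 <= k <= self.n_features_in_:
            raise ValueError(f"k={k} outside [1, {self.n_features_in_}]")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask


@dataclass
class IfsResult:
    """Outcome of an incremental feature selection sweep."""

    prefix_sizes: np.ndarray  # evaluated prefix sizes, increasing
    scores: np.ndarray  # evaluator score per prefix
    optimal_size: int  # smallest maximizing prefix size
    optimal_features: np.ndarray  # ranked feature indices of the optimal prefix

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"prefix_size": self.prefix_sizes, "score": self.scores})


def incremental_feature_selection(
    ranking: Sequence[int],
    X: np.ndarray,
    y: np.ndarray,
    evaluator: Callable[[np.ndarray, np.ndarray], float],
    stride: int = 1,
) -> IfsResult:
    """Evaluate growing prefixes of a ranked feature list and pick the best.

    ``evaluator(X_subset, y) -> scalar score`` (typically a cross-validated
    mean AUC). With ``stride`` = 1 every prefix Set_1 … Set_D is evaluated;
    a larger stride evaluates a coarser grid (always including size D).
    Ties go to the smallest prefix. Any evaluator exception aborts with the
    offending prefix size in the message.
    """
    ranking = np.asarray(ranking, dtype=int)
    X = np.asarray(X)
    D = ranking.size
    if D == 0:
        raise ValueError("empty ranking")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sizes = list(range(1, D + 1, stride))
    if sizes[-1] != D:
        sizes.append(D)
    scores = []
    for size in sizes:
        cols = ranking[:size]
        try:
            scores.append(float(evaluator(X[:, cols], y)))
        except Exception as exc:  # re-raise with context, do not swallow
            raise RuntimeError(f"IFS evaluator failed at prefix size {size}") from exc
    scores_arr = np.asarray(scores)
    best = int(np.argmax(scores_arr))  # argmax takes the first (smallest) on ties
    return IfsResult(
        prefix_sizes=np.asarray(sizes),
        scores=scores_arr,
        optimal_size=int(sizes[best]),
        optimal_features=ranking[: sizes[best]].copy(),
    )
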