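"""Indicator-importance analysis: correlations and k-means grouping.

Ranks the seven training indicators by the absolute Pearson correlation of
each indicator's score column with a forecast outcome (by default the
fitted model's continuous decision margin), and groups the indicators by
1-D k-means on those correlation values (k = 3 splits them into strong /
moderate / weak contributors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .errors import DegenerateInputError
from .pipeline import FittedModel, decision_margin
from .scoring import INDICATORS
from .synth import SessionTable

__all__ = [
    "pearson",
    "CorrelationReport",
    "indicator_correlations",
    "ClusterAssignment",
    "cluster_indicators",
    "forecast_correlations",
]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two non-constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("Pearson correlation is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationReport:
    """Per-indicator correlations with an outcome, ranked by |r|."""

    correlations: dict[str, float]
    n: int
    ranking: tuple[str, ...]

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranking[:k]


def indicator_correlations(table, outcomes) -> CorrelationReport:
    """Correlate each indicator column with an outcome vector.

    ``table`` may be a :class:`SessionTable` or a plain V×7 score matrix.
    A constant indicator column yields NaN (and ranks last) rather than an
    error, since a degenerate column is an empirical fact of the sample.
    """
    scores = table.scores if isinstance(table, SessionTable) else np.asarray(table)
    outcomes = np.asarray(outcomes, dtype=float)
    if outcomes.shape != (scores.shape[0],):
        raise ValueError("outcomes must have one value per row")
    corr = {}
    for k, name in enumerate(INDICATORS):
        column = scores[:, k].astype(float)
        try:
            corr[name] = pearson(column, outcomes)
        except DegenerateInputError:
            corr[name] = float("nan")
    ranking = tuple(
        sorted(corr, key=lambda name: (np.isnan(corr[name]), -abs(corr[name])))
    )
    return CorrelationReport(corr, int(outcomes.size), ranking)


@dataclass(frozen=True)
class ClusterAssignment:
    """Indicator → cluster map from k-means on per-indicator features."""

    assignment: dict[str, int]
    k: int
    centroids: np.ndarray

    def groups(self) -> tuple[frozenset, ...]:
        """Cluster memberships as unordered sets of indicator names."""
        return tuple(
            frozenset(name for name, c in self.assignment.items() if c == cluster)
            for cluster in range(self.k)
        )


def cluster_indicators(features, k: int = 3, seed: int | None = 0) -> ClusterAssignment:
    """k-means over per-indicator feature vectors (20 seeded restarts).

    ``features`` maps indicator name → scalar or vector (typically the 1-D
    correlation value).  Clusters are relabelled in descending order of
    centroid mean, so cluster 0 is the strongest group.
    """
    if isinstance(features, Mapping):
        names = list(features)
        X = np.atleast_2d(np.asarray([np.atleast_1d(features[n]) for n in names], dtype=float))
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(INDICATORS[: X.shape[0]]) if X.shape[0] <= len(INDICATORS) else [
            str(i) for i in range(X.shape[0])
        ]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must lie in [1, {X.shape[0]}], got {k}")
    km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(X)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    assignment = {name: relabel[int(c)] for name, c in zip(names, km.labels_)}
    centroids = km.cluster_centers_[order]
    return ClusterAssignment(assignment, k, centroids)


def forecast_correlations(model: FittedModel, table: SessionTable, rows=None,
                          target: str = "margin") -> CorrelationReport:
    """Correlate indicators with the fitted forecaster's output.

    ``target="margin"`` uses the continuous decision margin (default);
    ``target="prediction"`` uses the binary predicted class.  ``rows``
    restricts the analysis to a subset of row indices (e.g. one split).
    """
    scores = table.scores
    if rows is not None:
        scores = scores[np.asarray(rows)]
    if target == "margin":
        outcome = decision_margin(model, scores)
    elif target == "prediction":
        from .pipeline import predict

        outcome = np.asarray(predict(model, scores), dtype=float)
    else:
        raise ValueError(f"unknown target {target!r}; expected 'margin' or 'prediction'")
    return indicator_correlations(scores, outcome)
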