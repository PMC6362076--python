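"""Local outlier factor (LOF) scoring from first principles.

LOF is a density-ratio anomaly score: for each subject, the average local
reachability density of its k-nearest neighbors is divided by the subject's
own. Scores near 1 mean the subject sits in a region as dense as its
neighbors'; scores well above 1 mean relative isolation. Definitions:

* k-distance(p): distance to the k-th nearest other point.
* N_k(p): every point within k-distance(p) — tie-inclusive, so |N_k(p)| >= k.
* reach_k(p, o) = max(k-distance(o), d(p, o)).
* lrd(p) = |N_k(p)| / sum_{o in N_k(p)} reach_k(p, o).
* LOF(p) = mean_{o in N_k(p)} lrd(o) / lrd(p).

Duplicate convention: a group of >= k+1 coincident points has reachability
sum 0; those points receive LOF = 1 exactly (a maximally dense clump is not
an outlier). Elsewhere an epsilon floor (1e-12) on the reachability sum keeps
densities finite.

The main scorer builds the full pairwise Euclidean distance matrix and
vectorizes the rest — exact and fast for cohort-scale n (up to ~10^4
subjects; memory is O(n^2)). ``naive_lof_oracle`` re-evaluates the same
definitions in literal pure-Python loops and exists only as an independent
cross-check for the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: floor applied to reachability sums outside the coincident-group case
REACH_EPS = 1e-12


@dataclass
class StandardizedMatrix:
    """Z-scored feature matrix retaining the per-feature means/SDs.

    ``values`` holds only the retained (non-constant) columns; zero-variance
    columns are recorded in ``zero_variance`` and excluded from distance
    computation, but their means are kept so the inverse transform can
    rebuild the full input table.
    """

    values: np.ndarray
    feature_names: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    zero_variance: list[str]
    subject_ids: list

    def inverse(self) -> pd.DataFrame:
        """Undo the z-scoring, restoring constant columns from their means."""
        out = {}
        retained = {name: self.values[:, j] for j, name in enumerate(self.feature_names)}
        for name in list(self.means):
            if name in retained:
                out[name] = retained[name] * self.sds[name] + self.means[name]
            else:
                out[name] = np.full(len(self.values), self.means[name])
        return pd.DataFrame(out, index=pd.Index(self.subject_ids, name="subject_id"))


@dataclass
class NeighborhoodIndex:
    """Tie-inclusive k-nearest neighborhoods with per-point k-distances."""

    k: int
    k_distances: np.ndarray
    neighbors: list[np.ndarray]
    metric: str
    distances: np.ndarray  # full pairwise matrix, diagonal set to +inf


@dataclass
class LOFResult:
    """Per-subject LOF scores with the settings that produced them."""

    scores: np.ndarray
    k: int
    metric: str
    standardized: bool
    subject_ids: list

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.scores, index=pd.Index(self.subject_ids, name="subject_id"),
            name="lof_score",
        )


def standardize(features: pd.DataFrame) -> StandardizedMatrix:
    """Column-wise z-scoring (population SD); constant columns flagged and dropped.

    Raises ``TypeError`` naming any non-numeric column and ``ValueError`` if
    fewer than two rows or no column has variance.
    """
    if len(features) < 2:
        raise ValueError("standardization requires at least 2 rows")
    for name in features.columns:
        if not np.issubdtype(features[name].dtype, np.number):
            raise TypeError(f"non-numeric column: {name!r}")
    values = features.to_numpy(dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=0)
    zero_var = [name for name, sd in zip(features.columns, sds) if sd == 0.0]
    if len(zero_var) == len(features.columns):
        raise ValueError("all columns are zero-variance; nothing to standardize")
    if zero_var:
        logger.warning(
            "excluding %d zero-variance column(s) from distances: %s",
            len(zero_var), ", ".join(zero_var),
        )
    keep = [j for j, name in enumerate(features.columns) if name not in zero_var]
    z = (values[:, keep] - means[keep]) / sds[keep]
    return StandardizedMatrix(
        values=z,
        feature_names=[features.columns[j] for j in keep],
        means=dict(zip(features.columns, means)),
        sds=dict(zip(features.columns, sds)),
        zero_variance=zero_var,
        subject_ids=list(features.index),
    )


def _as_array(X) -> tuple[np.ndarray, list, bool]:
    if isinstance(X, StandardizedMatrix):
        return X.values, X.subject_ids, True
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index), False
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, list(range(len(arr))), False


def build_neighborhoods(X, k: int) -> NeighborhoodIndex:
    """Tie-inclusive k-nearest neighborhoods under Euclidean distance.

    ``k_distance`` is the distance to the k-th nearest other point; the
    neighbor set contains every other point at distance <= k_distance, so it
    can exceed k under ties. Requires 1 <= k <= n-1.
    """
    arr, _, _ = _as_array(X)
    n = len(arr)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}] for n={n}, got {k}")
    dist = squareform(pdist(arr, metric="euclidean"))
    np.fill_diagonal(dist, np.inf)
    # k-th smallest distance per row (self excluded via the inf diagonal)
    kdist = np.partition(dist, k - 1, axis=1)[:, k - 1]
    neighbors = [np.flatnonzero(dist[i] <= kdist[i]) for i in range(n)]
    return NeighborhoodIndex(
        k=k, k_distances=kdist, neighbors=neighbors,
        metric="euclidean", distances=dist,
    )


def lof_scores(X, k: int) -> LOFResult:
    """LOF scores for every subject; accepts a StandardizedMatrix, DataFrame or array."""
    arr, subject_ids, standardized = _as_array(X)
    index = build_neighborhoods(arr, k)
    n = len(arr)

    counts = np.array([len(nb) for nb in index.neighbors])
    flat = np.concatenate(index.neighbors)
    rows = np.repeat(np.arange(n), counts)
    reach = np.maximum(index.k_distances[flat], index.distances[rows, flat])
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    reach_sums = np.add.reduceat(reach, starts)

    lrd = counts / np.maximum(reach_sums, REACH_EPS)
    scores = np.add.reduceat(lrd[flat], starts) / counts / lrd
    scores[reach_sums == 0.0] = 1.0  # coincident group of >= k+1 points
    return LOFResult(
        scores=scores, k=k, metric=index.metric,
        standardized=standardized, subject_ids=subject_ids,
    )


def score_features(
    features: pd.DataFrame, k: int, *, standardize_first: bool = True
) -> LOFResult:
    """Standardize a raw feature table (by default) and score it."""
    if standardize_first:
        return lof_scores(standardize(features), k)
    return lof_scores(features, k)


def naive_lof_oracle(X, k: int) -> LOFResult:
    """Literal, unoptimized evaluation of the LOF definitions (test oracle).

    Pure-Python loops over the definitions; O(n^2) distances with no shared
    code path with :func:`lof_scores` beyond input handling. Intended for
    n up to a few thousand, in tests only.
    """
    arr, subject_ids, standardized = _as_array(X)
    n = len(arr)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}] for n={n}, got {k}")
    pts = [tuple(row) for row in arr]

    def dist(i, j):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(pts[i], pts[j])))

    kdist = []
    neighborhoods = []
    for i in range(n):
        ds = sorted((dist(i, j), j) for j in range(n) if j != i)
        kd = ds[k - 1][0]
        kdist.append(kd)
        neighborhoods.append([j for d, j in ds if d <= kd])

    lrd = []
    for i in range(n):
        total = sum(max(kdist[o], dist(i, o)) for o in neighborhoods[i])
        lrd.append(len(neighborhoods[i]) / max(total, REACH_EPS))

    scores = []
    for i in range(n):
        total = sum(max(kdist[o], dist(i, o)) for o in neighborhoods[i])
        if total == 0.0:
            scores.append(1.0)
        else:
            scores.append(
                sum(lrd[o] for o in neighborhoods[i]) / len(neighborhoods[i]) / lrd[i]
            )
    return LOFResult(
        scores=np.array(scores), k=k, metric="euclidean",
        standardized=standardized, subject_ids=subject_ids,
    )
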