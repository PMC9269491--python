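"""Collaborative clustering of activity timespan vectors.

Each (day, period) that survived day filtering is summarised as a *timespan
vector*: over the period's fixed activity vocabulary, the mean duration in
minutes of each activity that day (0 for absent activities; repeats within
a day are averaged). Two clusterings are run in parallel on the vectors of
each period:

* K-Means with DTW assignment — Lloyd iterations where each vector joins
  the centroid minimising DTW distance and centroids are element-wise means
  (vectors share a vocabulary, so they are equal-length and the classical
  mean update applies), k-means++ initialisation, seeded restarts;
* agglomerative hierarchical clustering — Manhattan distance, average
  linkage (Ward would require Euclidean geometry), via scipy's linkage.

Cluster counts are chosen by scanning validity indices: mean silhouette
(Davies-Bouldin as tie-break) for K-Means, Dunn index for the hierarchy.

Each route then filters days:

* *centroid-ratio filter* (K-Means): a vector passes when every activity
  performed that day has a duration within ``centroid * (1 +/- alpha)`` of
  its cluster centroid — durations below the centroid are checked against
  the lower half-range, durations above against the upper;
* *representative-cluster filter* (agglomerative): vectors in clusters
  smaller than the minimum acceptance size are discarded.

The two day sets are finally combined by union (default; gives the best
history coverage) or intersection.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score as _sk_silhouette

from .day_filtering import FilteredDaySet
from .distances import dtw_distance, get_metric, pairwise_distances
from .log_io import PeriodSequence

__all__ = [
    "TimespanVector",
    "ClusteringResult",
    "TimespanRange",
    "build_vectors",
    "kmeans_dtw",
    "agglomerative_manhattan",
    "silhouette_score",
    "davies_bouldin",
    "dunn_index",
    "select_k_kmeans",
    "select_k_agglomerative",
    "centroid_ratio_filter",
    "representative_cluster_filter",
    "combine",
]

DaySegments = Mapping[datetime.date, Mapping[str, PeriodSequence]]


@dataclass
class TimespanVector:
    """Mean activity durations of one (day, period) over a fixed vocabulary."""

    day_id: datetime.date
    period: str
    vocabulary: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.vocabulary):
            raise ValueError("values and vocabulary must be parallel")


@dataclass
class ClusteringResult:
    """Cluster assignment of a list of timespan vectors."""

    labels: np.ndarray
    k: int
    method: str
    centroids: np.ndarray | None = None
    merge_heights: np.ndarray | None = None  # agglomerative only
    inertia: float | None = None  # kmeans only: sum of assignment distances
    objective_history: list[float] | None = None  # kmeans only, non-increasing


@dataclass(frozen=True)
class TimespanRange:
    """Allowed duration band ``centroid * (1 +/- alpha)`` for one activity."""

    activity: str
    period: str
    low: float
    high: float
    centroid_value: float

    def __post_init__(self) -> None:
        if not (self.low <= self.centroid_value <= self.high):
            raise ValueError("need low <= centroid <= high")

    def contains(self, minutes: float) -> bool:
        if minutes < self.centroid_value:  # lower half-range
            return minutes >= self.low
        return minutes <= self.high  # upper half-range


def build_vectors(
    segments: DaySegments,
    day_ids: Iterable[datetime.date],
    period: str,
) -> list[TimespanVector]:
    """One timespan vector per (day, period), repeats averaged.

    The vocabulary is the union of the period's labels over the given days,
    ordered by first appearance scanning days chronologically; it is shared
    by every returned vector so they are equal-length. Days whose period
    sequence is empty yield no vector.
    """
    days = sorted(day_ids)
    vocab: dict[str, None] = {}
    for day_id in days:
        seq = segments[day_id].get(period)
        if seq is not None:
            for label in seq.labels:
                vocab.setdefault(label, None)
    vocabulary = tuple(vocab)
    index = {label: i for i, label in enumerate(vocabulary)}
    out: list[TimespanVector] = []
    for day_id in days:
        seq = segments[day_id].get(period)
        if seq is None or not len(seq):
            continue
        sums = np.zeros(len(vocabulary))
        counts = np.zeros(len(vocabulary))
        for label, dur in zip(seq.labels, seq.durations):
            sums[index[label]] += dur
            counts[index[label]] += 1
        values = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
        out.append(TimespanVector(day_id, period, vocabulary, values))
    return out


def _as_matrix(vectors: Sequence[TimespanVector]) -> np.ndarray:
    return np.stack([v.values for v in vectors])


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under DTW distance."""
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    d2 = np.array([dtw_distance(x, centroids[0]) for x in X]) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centroids.append(X[idx])
        d_new = np.array([dtw_distance(x, centroids[-1]) for x in X]) ** 2
        d2 = np.minimum(d2, d_new)
    return np.stack(centroids)


def kmeans_dtw(
    vectors: Sequence[TimespanVector],
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 50,
) -> ClusteringResult:
    """Lloyd K-Means with DTW assignment and element-wise mean centroids.

    k-means++ initialisation; ``n_restarts`` seeded restarts keep the run
    with the lowest objective (sum of assignment distances, non-increasing
    across iterations). Clusters that lose all members are dropped, so the
    effective ``k`` of the result can be smaller than requested.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(vectors):
        raise ValueError(f"k={k} exceeds the number of vectors ({len(vectors)})")
    X = _as_matrix(vectors)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng((seed, restart))
        centroids = _kmeans_pp_init(X, k, rng) if k > 1 else X.mean(0, keepdims=True)
        labels: np.ndarray | None = None
        history: list[float] = []
        for _ in range(max_iter):
            dists = np.array([[dtw_distance(x, c) for c in centroids] for x in X])
            obj = float(dists.min(axis=1).sum())
            # stop once the assignment objective no longer improves (the
            # element-wise mean update is not the exact DTW barycentre, so
            # this also guarantees termination)
            if history and obj >= history[-1] - 1e-9:
                break
            history.append(obj)
            new_labels = dists.argmin(axis=1)
            # drop empty clusters, relabel compactly
            used = np.unique(new_labels)
            remap = {old: new for new, old in enumerate(used)}
            new_labels = np.array([remap[l] for l in new_labels])
            centroids = np.stack([X[new_labels == c].mean(0) for c in range(len(used))])
            if labels is not None and np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        inertia = float(sum(dtw_distance(x, centroids[l]) for x, l in zip(X, labels)))
        if best is None or inertia < best[0]:
            best = (inertia, labels, centroids, history)
    inertia, labels, centroids, history = best
    return ClusteringResult(
        labels=labels,
        k=len(centroids),
        method="kmeans_dtw",
        centroids=centroids,
        inertia=inertia,
        objective_history=history,
    )


def agglomerative_manhattan(
    vectors: Sequence[TimespanVector], k: int
) -> ClusteringResult:
    """Bottom-up average-linkage clustering under Manhattan distance.

    Returns compact cluster labels plus the linkage merge heights (the
    dendrogram's vertical distances). Deterministic. Note that when merge
    heights tie (e.g. identical vectors) the flat cut may return fewer
    than ``k`` clusters.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(vectors):
        raise ValueError(f"k={k} exceeds the number of vectors ({len(vectors)})")
    X = _as_matrix(vectors)
    if len(X) == 1 or k == 1:
        return ClusteringResult(np.zeros(len(X), int), 1, "agglomerative_manhattan")
    Z = linkage(X, method="average", metric="cityblock")
    raw = fcluster(Z, t=k, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)
    return ClusteringResult(
        labels=labels,
        k=int(labels.max()) + 1,
        method="agglomerative_manhattan",
        merge_heights=Z[:, 2].copy(),
    )


def silhouette_score(
    X: np.ndarray | Sequence[TimespanVector],
    labels: Sequence[int],
    metric: str = "manhattan",
) -> float:
    """Mean silhouette ``s(i) = (b - a) / max(a, b)`` in [-1, 1].

    Singleton clusters score 0; with fewer than two clusters the score is
    0 by convention (no separation to measure).
    """
    X = _coerce(X)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return 0.0
    D = pairwise_distances(X, metric)
    return float(_sk_silhouette(D, labels, metric="precomputed"))


def davies_bouldin(
    X: np.ndarray | Sequence[TimespanVector],
    labels: Sequence[int],
    centroids: np.ndarray | None = None,
    metric: str = "manhattan",
) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    ``(scatter_i + scatter_j) / d(centroid_i, centroid_j)``; lower is
    better, >= 0. Scatter is the mean member-to-centroid distance."""
    X = _coerce(X)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        return 0.0
    dist = get_metric(metric)
    if centroids is None:
        centroids = np.stack([X[labels == c].mean(0) for c in clusters])
    scatter = np.array(
        [
            np.mean([dist(x, centroids[i]) for x in X[labels == c]])
            for i, c in enumerate(clusters)
        ]
    )
    worst = []
    for i in range(len(clusters)):
        ratios = [
            (scatter[i] + scatter[j]) / dist(centroids[i], centroids[j])
            for j in range(len(clusters))
            if j != i and dist(centroids[i], centroids[j]) > 0
        ]
        worst.append(max(ratios) if ratios else 0.0)
    return float(np.mean(worst))


def dunn_index(
    X: np.ndarray | Sequence[TimespanVector],
    labels: Sequence[int],
    metric: str = "manhattan",
) -> float:
    """Dunn index: min inter-cluster distance / max intra-cluster diameter.

    Inter-cluster distance is the minimum pairwise distance between members
    of different clusters; diameter is the maximum pairwise distance within
    a cluster. A partition with zero maximum diameter but positive
    separation returns ``inf``; all-identical data returns 0.
    """
    X = _coerce(X)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return 0.0
    D = pairwise_distances(X, metric)
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    intra = D[same & off_diag]
    inter = D[~same]
    diameter = float(intra.max()) if intra.size else 0.0
    separation = float(inter.min())
    if diameter == 0.0:
        return math.inf if separation > 0 else 0.0
    return separation / diameter


def _coerce(X) -> np.ndarray:
    if len(X) and isinstance(X[0], TimespanVector):
        return _as_matrix(X)
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def default_k_range(n: int) -> list[int]:
    """The scanned cluster counts: k in [2, n/2] (collapses to {2})."""
    return list(range(2, max(n // 2, 2) + 1))


def select_k_kmeans(
    vectors: Sequence[TimespanVector],
    k_range: Sequence[int] | None = None,
    seed: int = 0,
) -> tuple[int, ClusteringResult, list[dict]]:
    """Scan k maximising mean silhouette (DTW), Davies-Bouldin tie-break.

    Returns the chosen k, its clustering and the per-k report (one row per
    scanned k with silhouette and Davies-Bouldin values).
    """
    ks = list(k_range) if k_range is not None else default_k_range(len(vectors))
    ks = [k for k in ks if 2 <= k <= len(vectors)] or [min(2, len(vectors))]
    report: list[dict] = []
    results: dict[int, ClusteringResult] = {}
    for k in ks:
        res = kmeans_dtw(vectors, k, seed=seed)
        sil = silhouette_score(vectors, res.labels, metric="dtw")
        db = davies_bouldin(vectors, res.labels, res.centroids, metric="dtw")
        report.append({"k": k, "silhouette": sil, "davies_bouldin": db})
        results[k] = res
    best = max(report, key=lambda r: (r["silhouette"], -r["davies_bouldin"], -r["k"]))
    return best["k"], results[best["k"]], report


def select_k_agglomerative(
    vectors: Sequence[TimespanVector],
    k_range: Sequence[int] | None = None,
) -> tuple[int, ClusteringResult, list[dict]]:
    """Scan k maximising the Dunn index (Manhattan), DB tie-break.

    The returned clustering carries the linkage merge heights for
    dendrogram rendering.
    """
    ks = list(k_range) if k_range is not None else default_k_range(len(vectors))
    ks = [k for k in ks if 2 <= k <= len(vectors)] or [min(2, len(vectors))]
    report: list[dict] = []
    results: dict[int, ClusteringResult] = {}
    for k in ks:
        res = agglomerative_manhattan(vectors, k)
        dunn = dunn_index(vectors, res.labels, metric="manhattan")
        db = davies_bouldin(vectors, res.labels, metric="manhattan")
        report.append({"k": k, "dunn": dunn, "davies_bouldin": db})
        results[k] = res
    best = max(report, key=lambda r: (r["dunn"], -r["davies_bouldin"], -r["k"]))
    return best["k"], results[best["k"]], report


def centroid_ratio_filter(
    vectors: Sequence[TimespanVector],
    result: ClusteringResult,
    alpha: float = 0.2,
) -> tuple[set[tuple[datetime.date, str]], dict]:
    """Retain (day, period) vectors whose performed activities all stay
    within ``centroid * (1 +/- alpha)`` of their cluster centroid.

    Zero entries (activities absent that day) are not checked; a performed
    activity whose centroid entry is zero fails (no meaningful ratio).
    Returns the retained key set and a per-key failure report.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if result.centroids is None:
        raise ValueError("centroid_ratio_filter needs a centroid-based clustering")
    retained: set[tuple[datetime.date, str]] = set()
    failures: dict[tuple[datetime.date, str], list[str]] = {}
    for vec, label in zip(vectors, result.labels):
        centroid = result.centroids[label]
        bad: list[str] = []
        for i, activity in enumerate(vec.vocabulary):
            v = vec.values[i]
            if v == 0:
                continue
            c = centroid[i]
            if c == 0:
                bad.append(activity)
                continue
            rng = TimespanRange(activity, vec.period, c * (1 - alpha), c * (1 + alpha), c)
            if not rng.contains(v):
                bad.append(activity)
        key = (vec.day_id, vec.period)
        if bad:
            failures[key] = bad
        else:
            retained.add(key)
    return retained, failures


def representative_cluster_filter(
    vectors: Sequence[TimespanVector],
    result: ClusteringResult,
    min_size_frac: float = 0.10,
) -> tuple[set[tuple[datetime.date, str]], dict]:
    """Retain vectors belonging to representative clusters.

    A cluster is representative when its size is at least
    ``max(2, ceil(min_size_frac * N))``; members of smaller clusters (e.g.
    a day stranded in its own singleton) are discarded.
    """
    n = len(vectors)
    min_size = max(2, math.ceil(min_size_frac * n))
    sizes = np.bincount(result.labels, minlength=result.k)
    retained: set[tuple[datetime.date, str]] = set()
    rejected: dict[tuple[datetime.date, str], int] = {}
    for vec, label in zip(vectors, result.labels):
        key = (vec.day_id, vec.period)
        if sizes[label] >= min_size:
            retained.add(key)
        else:
            rejected[key] = int(sizes[label])
    return retained, rejected


def combine(
    day_set_kmeans: FilteredDaySet,
    day_set_agglomerative: FilteredDaySet,
    mode: str = "union",
) -> FilteredDaySet:
    """Combine the two routes' surviving-day sets (union or intersect)."""
    if mode not in ("union", "intersect"):
        raise ValueError(f"mode must be 'union' or 'intersect', got {mode!r}")
    a, b = day_set_kmeans.day_ids, day_set_agglomerative.day_ids
    days = (a | b) if mode == "union" else (a & b)
    out = FilteredDaySet(day_ids=set(days))
    for d in days:
        out.provenance[d] = {
            "kmeans": d in a,
            "agglomerative": d in b,
            "mode": mode,
        }
    return out
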