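"""Timespan vectors, DTW K-Means, agglomerative clustering, validity
indices and the two day filters."""

import datetime
import math

import numpy as np
import pytest
from sklearn.metrics import davies_bouldin_score

from routinemine.clustering import (
    ClusteringResult,
    TimespanVector,
    agglomerative_manhattan,
    build_vectors,
    centroid_ratio_filter,
    combine,
    davies_bouldin,
    default_k_range,
    dunn_index,
    kmeans_dtw,
    representative_cluster_filter,
    select_k_agglomerative,
    select_k_kmeans,
    silhouette_score,
)
from routinemine.day_filtering import FilteredDaySet
from routinemine.distances import dtw_distance
from routinemine.log_io import ActivityRecord, DayLog, split_days

from conftest import planted_vectors

D1 = datetime.date(2021, 3, 1)


def _vec(values, day=D1, period="night"):
    values = np.asarray(values, dtype=float)
    return TimespanVector(day, period, tuple(f"a{i}" for i in range(len(values))), values)


# --- vectors -----------------------------------------------------------------


def test_build_vectors_averages_repeats_and_zeroes_absent():
    """Toileting done twice (8 and 12 min) averages to 10; an activity
    absent that day gets a zero entry."""
    def rec(day, label, h, m, dur):
        t0 = datetime.datetime.combine(day, datetime.time(h, m))
        return ActivityRecord(label, t0, t0 + datetime.timedelta(minutes=dur))

    d2 = D1 + datetime.timedelta(days=1)
    days = [
        DayLog(D1, [rec(D1, "Toileting", 8, 0, 8), rec(D1, "Wash", 8, 30, 15),
                    rec(D1, "Toileting", 9, 30, 12)]),
        DayLog(d2, [rec(d2, "Wash", 8, 40, 17)]),
    ]
    segments = split_days(days)
    vectors = build_vectors(segments, [D1, d2], "morning")
    assert vectors[0].vocabulary == ("Toileting", "Wash")
    assert vectors[0].values.tolist() == [10.0, 15.0]
    assert vectors[1].values.tolist() == [0.0, 17.0]


def test_build_vectors_empty_period_yields_nothing():
    days = [DayLog(D1, [])]
    assert build_vectors(split_days(days), [D1], "night") == []


# --- dtw ---------------------------------------------------------------------


def test_dtw_identity_symmetry_nonnegativity():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x, y = rng.normal(size=5), rng.normal(size=4)
        assert dtw_distance(x, x) == 0
        assert dtw_distance(x, y) == pytest.approx(dtw_distance(y, x))
        assert dtw_distance(x, y) >= 0


def test_dtw_known_value():
    # alignment of [0,0,1] vs [0,1]: warp the two zeros together
    assert dtw_distance([0.0, 0.0, 1.0], [0.0, 1.0]) == 0.0
    assert dtw_distance([1.0, 2.0], [1.0, 3.0]) == 1.0


# --- kmeans ------------------------------------------------------------------


def test_kmeans_separated_groups_perfect_split():
    vectors = [_vec([10, 20])] * 3 + [_vec([200, 300])] * 3
    res = kmeans_dtw(vectors, 2, seed=0)
    assert res.k == 2
    assert len(set(res.labels[:3])) == 1 and len(set(res.labels[3:])) == 1
    assert res.labels[0] != res.labels[3]
    got = {tuple(c) for c in res.centroids}
    assert got == {(10.0, 20.0), (200.0, 300.0)}


def test_kmeans_k1_centroid_is_global_mean():
    vectors = [_vec([0, 0]), _vec([10, 10])]
    res = kmeans_dtw(vectors, 1, seed=0)
    assert res.k == 1
    assert res.centroids[0].tolist() == [5.0, 5.0]


def test_kmeans_k_above_n_rejected():
    with pytest.raises(ValueError):
        kmeans_dtw([_vec([1])], 2, seed=0)


def test_kmeans_recovers_planted_regimes():
    vectors, truth = planted_vectors(
        [[480, 10], [300, 60], [600, 120]], per_regime=5, jitter_sd=2, seed=1
    )
    res = kmeans_dtw(vectors, 3, seed=0)
    # same partition as the planted regimes (up to label renaming)
    mapping = {}
    for lab, t in zip(res.labels, truth):
        mapping.setdefault(t, lab)
        assert mapping[t] == lab
    assert len(set(mapping.values())) == 3


def test_kmeans_objective_non_increasing_and_deterministic():
    vectors, _ = planted_vectors([[100, 10], [300, 50]], per_regime=7, seed=2)
    a = kmeans_dtw(vectors, 2, seed=5)
    b = kmeans_dtw(vectors, 2, seed=5)
    assert np.array_equal(a.labels, b.labels)
    hist = a.objective_history
    assert all(hist[i + 1] <= hist[i] + 1e-9 for i in range(len(hist) - 1))


# --- agglomerative -----------------------------------------------------------


def test_agglomerative_recovers_planted_regimes():
    vectors, truth = planted_vectors(
        [[480, 10], [300, 60], [600, 120]], per_regime=5, jitter_sd=2, seed=3
    )
    res = agglomerative_manhattan(vectors, 3)
    mapping = {}
    for lab, t in zip(res.labels, truth):
        mapping.setdefault(t, lab)
        assert mapping[t] == lab


def test_agglomerative_identical_vectors_collapse():
    """All-identical vectors merge at height zero; the flat cut returns a
    single (degenerate) cluster whatever k is requested."""
    vectors = [_vec([5, 5])] * 6
    res = agglomerative_manhattan(vectors, 3)
    assert res.k == 1
    assert (res.merge_heights == 0).all()


def test_agglomerative_exposes_merge_heights():
    vectors, _ = planted_vectors([[10], [100]], per_regime=3, jitter_sd=1, seed=4)
    res = agglomerative_manhattan(vectors, 2)
    assert res.merge_heights is not None and len(res.merge_heights) == 5
    assert res.merge_heights[-1] == max(res.merge_heights)


# --- validity indices --------------------------------------------------------

FIXTURE_X = np.array([[0.0], [1.0], [5.0], [6.0]])
FIXTURE_LABELS = [0, 0, 1, 1]


def test_silhouette_two_cluster_fixture():
    """Hand derivation: s = mean(4.5/5.5, 3.5/4.5, 3.5/4.5, 4.5/5.5)."""
    expected = (4.5 / 5.5 + 3.5 / 4.5) / 2
    assert silhouette_score(FIXTURE_X, FIXTURE_LABELS, "euclidean") == pytest.approx(expected)
    assert expected == pytest.approx(0.79798, abs=1e-5)


def test_silhouette_identical_points_zero():
    X = np.zeros((4, 2))
    assert silhouette_score(X, [0, 0, 1, 1]) == pytest.approx(0.0)


def test_silhouette_far_separation_approaches_one():
    X = np.array([[0.0], [0.001], [1e6], [1e6 + 0.001]])
    assert silhouette_score(X, [0, 0, 1, 1], "euclidean") > 0.999


def test_davies_bouldin_fixture_and_sklearn_agreement():
    """DB = (0.5 + 0.5) / 5 = 0.2 on the fixture; matches sklearn on
    Euclidean data."""
    assert davies_bouldin(FIXTURE_X, FIXTURE_LABELS, metric="euclidean") == pytest.approx(0.2)
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 3))
    labels = rng.integers(0, 3, size=20)
    assert davies_bouldin(X, labels, metric="euclidean") == pytest.approx(
        davies_bouldin_score(X, labels)
    )


def test_davies_bouldin_singleton_clusters_zero_scatter():
    X = np.array([[0.0], [7.0]])
    assert davies_bouldin(X, [0, 1], metric="euclidean") == pytest.approx(0.0)


def test_dunn_fixture_value():
    assert dunn_index(FIXTURE_X, FIXTURE_LABELS, "euclidean") == pytest.approx(4.0)


def test_dunn_zero_diameter_infinite():
    X = np.array([[0.0], [0.0], [9.0], [9.0]])
    assert dunn_index(X, [0, 0, 1, 1], "euclidean") == math.inf


def test_merging_regimes_worsens_davies_bouldin():
    vectors, truth = planted_vectors([[100], [300], [600]], per_regime=5, seed=6)
    X = np.stack([v.values for v in vectors])
    merged = np.where(truth == 2, 1, truth)  # fuse the two far regimes
    assert davies_bouldin(X, truth) < davies_bouldin(X, merged)


# --- k selection -------------------------------------------------------------


def test_default_k_range_collapses_for_tiny_n():
    assert default_k_range(4) == [2]
    assert default_k_range(14) == list(range(2, 8))


def test_select_k_kmeans_finds_planted_k():
    vectors, _ = planted_vectors(
        [[100, 5], [300, 40], [600, 90], [900, 150]], per_regime=4, jitter_sd=1, seed=7
    )
    k, res, report = select_k_kmeans(vectors, seed=0)
    assert k == 4 and res.k == 4
    assert {row["k"] for row in report} == set(range(2, 9))
    assert all({"k", "silhouette", "davies_bouldin"} <= set(r) for r in report)


def test_select_k_agglomerative_finds_planted_k_and_maximises_dunn():
    vectors, _ = planted_vectors(
        [[100, 5], [300, 40], [600, 90]], per_regime=5, jitter_sd=1, seed=8
    )
    k, res, report = select_k_agglomerative(vectors)
    assert k == 3
    best = max(report, key=lambda r: r["dunn"])
    assert best["k"] == 3
    assert res.merge_heights is not None


def test_select_k_two_identical_groups():
    vectors = [_vec([10, 10])] * 4 + [_vec([500, 500])] * 4
    k, _, _ = select_k_agglomerative(vectors)
    assert k == 2


# --- filters -----------------------------------------------------------------


def _result_with(labels, centroids):
    return ClusteringResult(
        labels=np.asarray(labels), k=len(centroids), method="kmeans_dtw",
        centroids=np.asarray(centroids, dtype=float),
    )


def test_centroid_ratio_threshold_arithmetic():
    """centroid 60, alpha 0.2: 75 min fails (>72), 50 min passes (>=48),
    the centroid itself always passes."""
    centroids = [[60.0]]
    for value, ok in [(75, False), (50, True), (60, True), (72, True), (47, False)]:
        vecs = [_vec([value])]
        retained, failures = centroid_ratio_filter(vecs, _result_with([0], centroids), 0.2)
        assert ((D1, "night") in retained) is ok, (value, failures)


def test_centroid_ratio_zero_entries():
    """Absent activities are not checked; a performed activity with a zero
    centroid entry fails."""
    vecs = [_vec([0, 30])]
    retained, _ = centroid_ratio_filter(vecs, _result_with([0], [[50, 30]]), 0.2)
    assert (D1, "night") in retained
    retained, failures = centroid_ratio_filter(vecs, _result_with([0], [[50, 0]]), 0.2)
    assert retained == set() and failures[(D1, "night")] == ["a1"]


def test_centroid_ratio_alpha_domain():
    with pytest.raises(ValueError):
        centroid_ratio_filter([_vec([1])], _result_with([0], [[1.0]]), 1.5)


def test_ratio_filter_keeps_regular_days_rejects_outliers():
    """With alpha covering the jitter, >=95% of regime days survive and
    every planted outlier fails."""
    vectors, _ = planted_vectors([[120, 30], [400, 80]], per_regime=20, jitter_sd=2, seed=9)
    # anomalous days sit near a regime (so they join its cluster without
    # dominating the centroid) but deviate far beyond alpha on one activity
    outliers = [
        _vec([170, 30], day=datetime.date(2021, 5, 1)),
        _vec([400, 35], day=datetime.date(2021, 5, 2)),
    ]
    all_vecs = vectors + outliers
    res = kmeans_dtw(all_vecs, 2, seed=0)
    retained, _ = centroid_ratio_filter(all_vecs, res, alpha=0.2)
    regular = {(v.day_id, v.period) for v in vectors}
    assert len(retained & regular) >= 0.95 * len(vectors)
    assert all((o.day_id, o.period) not in retained for o in outliers)


def test_representative_filter_drops_small_clusters():
    vectors = [_vec([10], day=D1 + datetime.timedelta(days=i)) for i in range(9)]
    lone = _vec([999], day=datetime.date(2021, 5, 1))
    labels = [0] * 9 + [1]
    res = ClusteringResult(np.array(labels), 2, "agglomerative_manhattan")
    retained, rejected = representative_cluster_filter(vectors + [lone], res, 0.10)
    assert (lone.day_id, "night") not in retained
    assert rejected[(lone.day_id, "night")] == 1
    assert len(retained) == 9


def test_representative_filter_single_cluster_keeps_all():
    vectors = [_vec([10], day=D1 + datetime.timedelta(days=i)) for i in range(5)]
    res = ClusteringResult(np.zeros(5, int), 1, "agglomerative_manhattan")
    retained, _ = representative_cluster_filter(vectors, res)
    assert len(retained) == 5


# --- combination -------------------------------------------------------------


def test_combine_set_algebra():
    d = [datetime.date(2021, 3, i) for i in range(1, 5)]
    a = FilteredDaySet(day_ids={d[0], d[1]})
    b = FilteredDaySet(day_ids={d[2], d[3]})
    assert combine(a, b, "intersect").day_ids == set()
    assert combine(a, b, "union").day_ids == set(d)
    same = FilteredDaySet(day_ids={d[0]})
    assert combine(same, same, "union").day_ids == combine(same, same, "intersect").day_ids
    mixed = FilteredDaySet(day_ids={d[0], d[2]})
    inter = combine(a, mixed, "intersect").day_ids
    union = combine(a, mixed, "union").day_ids
    assert inter <= a.day_ids <= union and inter <= mixed.day_ids <= union
    with pytest.raises(ValueError):
        combine(a, b, "xor")
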