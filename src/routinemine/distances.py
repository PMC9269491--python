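"""Distance functions for timespan-vector clustering.

Dynamic time warping (DTW) is used for K-Means cluster assignment and
Manhattan (city-block) distance for agglomerative clustering. The DTW here
is the classic unconstrained dynamic program with absolute-difference local
cost; timespan vectors are short (one entry per distinct activity of a
period), so the O(n*m) recurrence is computed directly in numpy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, squareform

__all__ = ["dtw_distance", "pairwise_distances", "get_metric"]


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Unconstrained DTW distance between two 1-D sequences.

    ``D[i, j] = |x_i - y_j| + min(D[i-1, j], D[i, j-1], D[i-1, j-1])``;
    returns ``D[n, m]``. Satisfies DTW(x, x) = 0, symmetry, non-negativity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("DTW requires non-empty sequences")
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.empty((n, m))
    acc[0, :] = cost[0, :].cumsum()
    acc[:, 0] = cost[:, 0].cumsum()
    for i in range(1, n):
        row = acc[i]
        prev = acc[i - 1]
        row[0] = prev[0] + cost[i, 0]
        for j in range(1, m):
            row[j] = cost[i, j] + min(prev[j], row[j - 1], prev[j - 1])
    return float(acc[-1, -1])


def manhattan(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(np.asarray(x, float) - np.asarray(y, float)).sum())


def euclidean(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(x, float) - np.asarray(y, float)))


_METRICS = {"dtw": dtw_distance, "manhattan": manhattan, "euclidean": euclidean}


def get_metric(name: str):
    """Look up a metric callable by name (dtw, manhattan, euclidean)."""
    try:
        return _METRICS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; choose from {sorted(_METRICS)}")


def pairwise_distances(X: np.ndarray, metric: str = "manhattan") -> np.ndarray:
    """Symmetric pairwise distance matrix over the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if metric == "manhattan":
        return cdist(X, X, metric="cityblock")
    if metric == "euclidean":
        return cdist(X, X, metric="euclidean")
    if metric == "dtw":
        n = X.shape[0]
        condensed = [
            dtw_distance(X[i], X[j]) for i in range(n) for j in range(i + 1, n)
        ]
        return squareform(np.asarray(condensed)) if n > 1 else np.zeros((1, 1))
    raise ValueError(f"unknown metric {metric!r}")
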