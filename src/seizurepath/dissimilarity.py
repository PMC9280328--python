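"""Pairwise seizure comparison measures.

Two seizures are compared in two complementary ways:

* **Pathway dissimilarity** — dynamic time warping (DTW) aligns the two
  connectivity time series so as to minimise the total L1 (cityblock)
  distance between matched windows; the dissimilarity is the *average* L1
  distance along the optimal alignment.  Warping lets two seizures that
  traverse the same sequence of network configurations at different speeds
  score as similar.
* **Duration difference** — |ln(l_i) - ln(l_j)| = |ln(l_i / l_j)|, the
  absolute difference of natural-log durations, which depends only on the
  duration *ratio* (20 s vs 40 s equals 60 s vs 120 s).

Collecting all pairs of a subject's ``s`` seizures yields symmetric ``s x s``
matrices with zero diagonal.  The duration matrix is a metric (it is an L1
distance on ln l); the pathway matrix need not satisfy the triangle
inequality because the normalising path length differs between pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .connectivity import ConnectivityTimeSeries

__all__ = [
    "DissimilarityMatrix",
    "dtw_dissimilarity",
    "pathway_dissimilarity_matrix",
    "duration_difference_matrix",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative pairwise matrix with zero diagonal."""

    values: np.ndarray
    seizure_ids: list
    kind: str  # "pathway" | "duration"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("dissimilarity matrix must be nonnegative")
        self.values = v
        if len(self.seizure_ids) != v.shape[0]:
            raise ValueError("seizure_ids length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        """Upper-triangular (i < j) entries as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@njit(cache=True)
def _dtw_core(cost: np.ndarray) -> tuple[float, int]:
    """DTW over a precomputed local-cost matrix with unit steps.

    Minimises total path cost; among minimal-cost paths, maximises the path
    length K (number of aligned pairs) so that cost/K, the average distance
    along the warped series, is well defined even under ties.  Both endpoints
    are anchored.  Returns (total cost, K).
    """
    mA, mB = cost.shape
    INF = np.inf
    acc = np.empty((mA, mB))
    length = np.zeros((mA, mB), dtype=np.int64)
    acc[0, 0] = cost[0, 0]
    length[0, 0] = 1
    for j in range(1, mB):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
        length[0, j] = j + 1
    for i in range(1, mA):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        length[i, 0] = i + 1
    for i in range(1, mA):
        for j in range(1, mB):
            best = acc[i - 1, j - 1]
            blen = length[i - 1, j - 1]
            for pi, pj in ((i - 1, j), (i, j - 1)):
                c = acc[pi, pj]
                ln = length[pi, pj]
                if c < best - 1e-15 or (c <= best + 1e-15 and ln > blen):
                    best = c
                    blen = ln
            acc[i, j] = best + cost[i, j]
            length[i, j] = blen + 1
    return acc[mA - 1, mB - 1], int(length[mA - 1, mB - 1])


def dtw_dissimilarity(P: ConnectivityTimeSeries, Q: ConnectivityTimeSeries) -> float:
    """Average L1 distance between two pathways after DTW alignment.

    Classic DTW with unit steps (match / insert / delete), endpoints
    anchored, local cost = cityblock distance between window feature
    vectors.  The total optimal path cost is divided by the warped length K
    (the number of aligned window pairs).
    """
    if P.features.shape[1] != Q.features.shape[1]:
        raise ValueError("pathways have different feature dimensions")
    if P.n_windows < 1 or Q.n_windows < 1:
        raise ValueError("pathways must have at least one window")
    cost = cdist(P.features, Q.features, metric="cityblock")
    total, k = _dtw_core(cost)
    return float(total / k)


def pathway_dissimilarity_matrix(
    pathways: dict[object, ConnectivityTimeSeries] | list[ConnectivityTimeSeries],
    seizure_ids: list | None = None,
) -> DissimilarityMatrix:
    """All-pairs DTW pathway dissimilarity matrix for one subject."""
    if isinstance(pathways, dict):
        seizure_ids = list(pathways)
        series = list(pathways.values())
    else:
        series = list(pathways)
        if seizure_ids is None:
            seizure_ids = list(range(len(series)))
    s = len(series)
    if s < 2:
        raise ValueError("need at least 2 seizures")
    for fc in series:
        if fc.n_windows < 1:
            raise ValueError("empty pathway")
    D = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            D[i, j] = D[j, i] = dtw_dissimilarity(series[i], series[j])
    return DissimilarityMatrix(D, seizure_ids, kind="pathway")


def duration_difference_matrix(
    durations_s, seizure_ids: list | None = None
) -> DissimilarityMatrix:
    """Pairwise |ln(l_i) - ln(l_j)| matrix of seizure durations."""
    durations = np.asarray(list(durations_s.values()) if isinstance(durations_s, dict)
                           else durations_s, dtype=float)
    if seizure_ids is None:
        seizure_ids = (list(durations_s) if isinstance(durations_s, dict)
                       else list(range(len(durations))))
    if (durations <= 0).any():
        raise ValueError("durations must be positive")
    logd = np.log(durations)
    D = np.abs(logd[:, None] - logd[None, :])
    return DissimilarityMatrix(D, seizure_ids, kind="duration")
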