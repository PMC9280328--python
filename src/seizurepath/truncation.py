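"""Detection of truncation pairs.

A truncation pair is a pair of seizures where one is a shortened version of
the other in *both* pathway and duration: the shorter seizure follows the
beginning of the longer seizure's route through network space and then stops
early.  Detection works on groups of near-identical pathways (UPGMA
dendrogram cut at pathway dissimilarity 1) to keep the DTW scan cheap: each
group is represented by its centroid seizure, and for an ordered group pair
(A, B) the criteria are

(i)   every seizure in A is shorter in duration than every seizure in B,
(ii)  every seizure in A has a smaller pathway size (maximum cityblock
      distance between any two of its windows) than every seizure in B, and
(iii) the partial-pathway dissimilarity between centroid A and the first
      ``m`` windows of centroid B drops to <= 1 for some ``m``.

If all three hold, every seizure of A is a truncated version of every seizure
of B, and all |A| x |B| pairs count as truncation pairs.  A subject's
truncation proportion is the fraction of its s(s-1)/2 pairs so flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .connectivity import ConnectivityTimeSeries
from .dissimilarity import DissimilarityMatrix, dtw_dissimilarity

__all__ = [
    "TruncationResult",
    "group_similar_pathways",
    "pathway_size",
    "partial_dissimilarity_profile",
    "find_truncation_pairs",
]


@dataclass
class TruncationResult:
    """Groups, flagged ordered group pairs and the pair-level truncation mask."""

    group_labels: np.ndarray  # per-seizure group id, 1..G
    centroids: dict[int, int]  # group id -> seizure index of the centroid
    flagged_group_pairs: list[tuple[int, int]]  # (truncated group, full group)
    pair_matrix: np.ndarray  # (s, s) bool; [i, j] True if i truncates j
    proportion: float
    pathway_sizes: np.ndarray = field(default=None)

    @property
    def n_truncation_pairs(self) -> int:
        return int(self.pair_matrix.sum())  # ordered pairs == unordered pairs here


def group_similar_pathways(
    D: DissimilarityMatrix | np.ndarray, cut: float = 1.0
) -> tuple[np.ndarray, dict[int, int]]:
    """UPGMA-cluster seizures and cut the dendrogram at dissimilarity ``cut``.

    Merges at height <= ``cut`` stay merged (inclusive).  Returns per-seizure
    group labels (1..G) and the centroid of each group — the member with the
    lowest mean dissimilarity to the rest of its group (a singleton is its
    own centroid).
    """
    values = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    s = values.shape[0]
    if s == 1:
        return np.array([1]), {1: 0}
    Z = linkage(squareform(values, checks=False), method="average")
    labels = fcluster(Z, t=cut, criterion="distance")
    centroids: dict[int, int] = {}
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        if members.size == 1:
            centroids[int(g)] = int(members[0])
        else:
            sub = values[np.ix_(members, members)]
            mean_d = sub.sum(axis=1) / (members.size - 1)
            centroids[int(g)] = int(members[np.argmin(mean_d)])
    return labels, centroids


def pathway_size(P: ConnectivityTimeSeries) -> float:
    """Maximum cityblock distance between any two windows of one pathway.

    Measures how far the seizure travels through network space.  A
    single-window pathway has size zero.
    """
    if P.n_windows < 1:
        raise ValueError("empty pathway")
    if P.n_windows == 1:
        return 0.0
    return float(pdist(P.features, metric="cityblock").max())


def partial_dissimilarity_profile(
    A: ConnectivityTimeSeries, B: ConnectivityTimeSeries
) -> np.ndarray:
    """DTW dissimilarity between A and each prefix of B.

    Entry ``m-1`` (m = 1..m_B) is the pathway dissimilarity between A and the
    first ``m`` windows of B.  A low minimum indicates that A matches the
    beginning of B.
    """
    return np.array(
        [dtw_dissimilarity(A, B.sliced(slice(0, m))) for m in range(1, B.n_windows + 1)]
    )


def find_truncation_pairs(
    pathways: list[ConnectivityTimeSeries],
    D: DissimilarityMatrix | np.ndarray,
    durations_s,
    cut: float = 1.0,
    dissim_thresh: float = 1.0,
) -> TruncationResult:
    """Flag all truncation pairs among a subject's seizures.

    Criteria (i) and (ii) compare group extrema with strict inequalities
    (ties fail); criterion (iii) is evaluated on group centroids only, and
    group members inherit the flag.
    """
    durations = np.asarray(list(durations_s.values()) if isinstance(durations_s, dict)
                           else durations_s, dtype=float)
    s = len(pathways)
    if s != durations.size:
        raise ValueError("pathways and durations disagree in length")
    labels, centroids = group_similar_pathways(D, cut=cut)
    sizes = np.array([pathway_size(p) for p in pathways])
    pair_matrix = np.zeros((s, s), dtype=bool)
    flagged: list[tuple[int, int]] = []
    groups = {int(g): np.flatnonzero(labels == g) for g in np.unique(labels)}
    profile_cache: dict[tuple[int, int], float] = {}
    for ga, mem_a in groups.items():
        for gb, mem_b in groups.items():
            if ga == gb:
                continue
            if not durations[mem_a].max() < durations[mem_b].min():
                continue
            if not sizes[mem_a].max() < sizes[mem_b].min():
                continue
            key = (centroids[ga], centroids[gb])
            if key not in profile_cache:
                prof = partial_dissimilarity_profile(
                    pathways[key[0]], pathways[key[1]]
                )
                profile_cache[key] = float(prof.min())
            if profile_cache[key] <= dissim_thresh:
                flagged.append((ga, gb))
                pair_matrix[np.ix_(mem_a, mem_b)] = True
    n_pairs = s * (s - 1) // 2
    proportion = float(pair_matrix.sum() / n_pairs) if n_pairs else 0.0
    return TruncationResult(
        group_labels=labels,
        centroids=centroids,
        flagged_group_pairs=flagged,
        pair_matrix=pair_matrix,
        proportion=proportion,
        pathway_sizes=sizes,
    )
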