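"""Duration populations and their agreement with pathway clusters.

Some subjects have distinct populations of short and long seizures.  These
are detected by k-means clustering of log-transformed durations with the
number of clusters chosen by the gap statistic (firstMaxSE rule, reference
datasets drawn uniformly over the observed range); k = 1 means no multiple
populations.  When k >= 2, the pathway dissimilarity matrix is UPGMA-cut
into the same number of clusters and the two partitions are compared with
the Rand index and adjusted Rand index, each with a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score, rand_score

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "ClusterPartition",
    "PartitionAgreement",
    "cluster_durations",
    "cluster_pathways",
    "partition_agreement",
]


@dataclass
class ClusterPartition:
    labels: np.ndarray  # 1..k per seizure
    k: int
    source: str  # "duration" | "pathway"
    gap: np.ndarray | None = None  # gap(k) curve, index 0 -> k=1
    gap_se: np.ndarray | None = None


@dataclass
class PartitionAgreement:
    rand_index: float
    adjusted_rand_index: float
    p_rand: float
    p_ari: float
    n_perm: int
    seed: int | None = None


def _kmeans_1d(
    X: np.ndarray, k: int, n_init: int, rng: np.random.Generator, max_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Lloyd's algorithm on 1-D data.

    ``X`` has shape (B, n): B independent datasets clustered simultaneously
    (used for the gap-statistic reference draws).  The first initialisation
    places centres at evenly spaced quantiles — in 1-D this lands near the
    optimum — and the remaining ``n_init - 1`` draw centres from the data.
    Returns (inertia (B,), labels (B, n)) of the best run per dataset.
    """
    B, n = X.shape
    best_inertia = np.full(B, np.inf)
    best_labels = np.zeros((B, n), dtype=int)
    rows = np.arange(B)[:, None]
    for init in range(n_init):
        if init == 0:
            q = (2 * np.arange(k) + 1) / (2 * k)
            C = np.quantile(X, q, axis=1).T  # (B, k)
        else:
            C = X[rows[:, 0][:, None], rng.integers(0, n, size=(B, k))]
        C = np.sort(C, axis=1)
        labels = None
        for _ in range(max_iter):
            d = np.abs(X[:, None, :] - C[:, :, None])  # (B, k, n)
            new_labels = d.argmin(axis=1)  # (B, n)
            if labels is not None and (new_labels == labels).all():
                break
            labels = new_labels
            sums = np.zeros((B, k))
            counts = np.zeros((B, k))
            np.add.at(sums, (rows.repeat(n, 1), labels), X)
            np.add.at(counts, (rows.repeat(n, 1), labels), 1.0)
            nonempty = counts > 0
            C = np.where(nonempty, sums / np.maximum(counts, 1), C)
        inertia = ((X - np.take_along_axis(C, labels, axis=1)) ** 2).sum(axis=1)
        better = inertia < best_inertia
        best_inertia[better] = inertia[better]
        best_labels[better] = labels[better]
    return best_inertia, best_labels


def cluster_durations(
    durations_s,
    k_max: int = 10,
    n_ref: int = 1000,
    n_init: int = 10,
    seed: int | None = None,
) -> ClusterPartition:
    """k-means clustering of log durations with gap-statistic model selection.

    k is scanned from 1 to ``min(s, k_max)``.  For each k the within-cluster
    dispersion ``W_k`` (sum of squared deviations from cluster means) of the
    observed log durations is compared against ``n_ref`` reference datasets
    drawn uniformly over the observed range:

        gap(k) = mean_ref[log W_k*] - log W_k,
        SE(k)  = sd_ref[log W_k*] * sqrt(1 + 1/n_ref).

    The chosen k is the smallest one with ``gap(k) >= gap(k+1) - SE(k+1)``
    (firstMaxSE); k = 1 indicates a single duration population.  The result
    is invariant to rescaling all durations, since that only shifts the log.
    """
    durations = np.asarray(list(durations_s.values()) if isinstance(durations_s, dict)
                           else durations_s, dtype=float)
    if (durations <= 0).any():
        raise ValueError("durations must be positive")
    s = durations.size
    if s < 2:
        raise ValueError("need at least 2 seizures")
    x = np.log(durations)
    k_hi = min(s, k_max)
    if np.ptp(x) == 0:  # all identical: no structure by definition
        return ClusterPartition(labels=np.ones(s, dtype=int), k=1, source="duration")
    rng = np.random.default_rng(seed)
    ref = rng.uniform(x.min(), x.max(), size=(n_ref, s))
    eps = 1e-12
    gap = np.empty(k_hi)
    se = np.empty(k_hi)
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, k_hi + 1):
        w_obs, lab = _kmeans_1d(x[None, :], k, n_init=n_init, rng=rng)
        labels_by_k[k] = lab[0] + 1
        w_ref, _ = _kmeans_1d(ref, k, n_init=1, rng=rng)
        log_ref = np.log(np.maximum(w_ref, eps))
        gap[k - 1] = log_ref.mean() - np.log(max(w_obs[0], eps))
        se[k - 1] = log_ref.std() * np.sqrt(1.0 + 1.0 / n_ref)
    k_sel = k_hi
    for k in range(1, k_hi):
        if gap[k - 1] >= gap[k] - se[k]:
            k_sel = k
            break
    return ClusterPartition(
        labels=labels_by_k[k_sel], k=k_sel, source="duration", gap=gap, gap_se=se
    )


def cluster_pathways(D_path, k: int) -> ClusterPartition:
    """UPGMA-cut the pathway dissimilarity matrix into exactly k clusters."""
    values = (D_path.values if isinstance(D_path, DissimilarityMatrix)
              else np.asarray(D_path, float))
    s = values.shape[0]
    if k > s:
        raise ValueError(f"cannot form {k} clusters from {s} seizures")
    if k == s:
        labels = np.arange(1, s + 1)
    else:
        Z = linkage(squareform(values, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterPartition(labels=np.asarray(labels, dtype=int), k=k, source="pathway")


def partition_agreement(
    p1: ClusterPartition | np.ndarray,
    p2: ClusterPartition | np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PartitionAgreement:
    """Rand index and ARI between two partitions, with permutation p-values.

    The null permutes the membership vector of the second partition; the
    one-sided p-value counts permuted statistics >= the observed one, with
    the add-one convention.
    """
    a = np.asarray(p1.labels if isinstance(p1, ClusterPartition) else p1)
    b = np.asarray(p2.labels if isinstance(p2, ClusterPartition) else p2)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same seizures")
    ri = rand_score(a, b)
    ari = adjusted_rand_score(a, b)
    rng = np.random.default_rng(seed)
    ge_ri = 0
    ge_ari = 0
    for _ in range(n_perm):
        perm = rng.permutation(b)
        if rand_score(a, perm) >= ri:
            ge_ri += 1
        if adjusted_rand_score(a, perm) >= ari:
            ge_ari += 1
    return PartitionAgreement(
        rand_index=float(ri),
        adjusted_rand_index=float(ari),
        p_rand=(ge_ri + 1) / (n_perm + 1),
        p_ari=(ge_ari + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )
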