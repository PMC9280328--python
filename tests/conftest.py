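import numpy as np
import pytest

from seizurepath import CohortConfig, ConnectivityTimeSeries, generate_cohort


def series_from_features(feats) -> ConnectivityTimeSeries:
    """Wrap a raw (m, F) array as a pathway for toy DTW/geometry tests.

    Uses a 2-channel montage (one channel pair) with F single-pair "bands"
    so any feature dimension is admissible.
    """
    feats = np.atleast_2d(np.asarray(feats, dtype=float))
    F = feats.shape[1]
    return ConnectivityTimeSeries(
        features=feats,
        n_channels=2,
        band_names=tuple(f"b{i}" for i in range(F)),
    )


def brute_force_dtw(cost: np.ndarray) -> float:
    """Exhaustive enumeration of all admissible unit-step warping paths.

    Returns min total cost divided by the maximal path length among
    minimal-cost paths — the independent oracle for the DTW dissimilarity.
    """
    mA, mB = cost.shape
    results: list[tuple[float, int]] = []

    def rec(i: int, j: int, total: float, k: int) -> None:
        total += cost[i, j]
        k += 1
        if i == mA - 1 and j == mB - 1:
            results.append((total, k))
            return
        if i + 1 < mA:
            rec(i + 1, j, total, k)
        if j + 1 < mB:
            rec(i, j + 1, total, k)
        if i + 1 < mA and j + 1 < mB:
            rec(i + 1, j + 1, total, k)

    rec(0, 0, 0.0, 0)
    min_cost = min(c for c, _ in results)
    best_k = max(k for c, k in results if c <= min_cost + 1e-12)
    return min_cost / best_k


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions, shared across tests."""
    return generate_cohort(CohortConfig(), seed=7)


@pytest.fixture(scope="session")
def small_cohort_config():
    """Reduced cohort for fast pipeline-level tests."""
    return CohortConfig(
        n_channels=8,
        n_pathways=2,
        seizures_per_pathway=3,
        n_elastic_pairs=1,
        n_semblant_pairs=1,
        n_truncation_pairs=1,
    )
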