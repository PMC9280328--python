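"""Sammon mapping of seizure time windows into the plane.

A 2-D embedding of all seizure windows is produced by minimising the Sammon
stress

    E = (1 / sum_ij d_ij) * sum_{i<j} (d_ij - delta_ij)^2 / d_ij,

where ``d_ij`` are the target (L1) distances between window connectivity
patterns and ``delta_ij`` the Euclidean distances in the embedding.  The
normalisation by ``d_ij`` weights small distances relatively more than plain
metric MDS, preserving local pathway structure.  Optimisation is plain
gradient descent with a step-halving line search, started from the classical
MDS solution, so the stress never increases across accepted iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["EmbeddingResult", "sammon_map"]


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n, dim)
    stress: float
    iterations: int
    seed: int | None = None


def _classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1][:dim]
    comp = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return comp


def _stress(D: np.ndarray, Y: np.ndarray, c: float, eps: float) -> float:
    delta = squareform(pdist(Y))
    iu = np.triu_indices(D.shape[0], k=1)
    d = np.maximum(D[iu], eps)
    return float(((d - delta[iu]) ** 2 / d).sum() / c)


def sammon_map(
    window_distances: np.ndarray,
    dim: int = 2,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
    eps: float = 1e-9,
) -> EmbeddingResult:
    """Embed points in ``dim`` dimensions by Sammon stress minimisation.

    ``window_distances`` is a symmetric nonnegative matrix with zero
    diagonal (here: L1 distances between window connectivity patterns).
    Zero off-diagonal targets are floored at ``eps``.  Initialisation is
    classical MDS, perturbed by a tiny seeded jitter to break exact
    degeneracies; descent steps are halved until the stress decreases, and
    iteration stops when the relative stress improvement falls below
    ``tol``.
    """
    D = np.asarray(window_distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    if n < 2 or not (D[iu] > 0).any():
        raise ValueError("need at least two distinct points")
    Dw = np.maximum(D, eps)
    np.fill_diagonal(Dw, 0.0)
    c = float(Dw[iu].sum())

    rng = np.random.default_rng(seed)
    Y = _classical_mds(D, dim)
    scale = max(Dw[iu].mean(), eps)
    Y = Y + rng.normal(scale=1e-6 * scale, size=Y.shape)

    stress = _stress(Dw, Y, c, eps)
    step = 0.3
    it = 0
    for it in range(1, max_iter + 1):
        delta = squareform(pdist(Y))
        np.fill_diagonal(delta, 1.0)
        delta = np.maximum(delta, eps)
        denom = Dw * delta
        np.fill_diagonal(denom, 1.0)  # diagonal weight is zeroed below
        W = (Dw - delta) / denom
        np.fill_diagonal(W, 0.0)
        # dE/dY_i = (-2/c) * sum_j W_ij (Y_i - Y_j)
        grad = (-2.0 / c) * (W.sum(axis=1, keepdims=True) * Y - W @ Y)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            break
        # step-halving line search: only accept a stress decrease
        accepted = False
        trial = step
        for _ in range(30):
            Y_new = Y - trial * grad
            s_new = _stress(Dw, Y_new, c, eps)
            if s_new < stress:
                accepted = True
                break
            trial /= 2.0
        if not accepted:
            break
        improvement = (stress - s_new) / max(stress, eps)
        Y, stress, step = Y_new, s_new, min(trial * 2.0, 1.0)
        if improvement < tol:
            break
    return EmbeddingResult(coordinates=Y, stress=stress, iterations=it, seed=seed)
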