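"""Stability NMF denoising of the concatenated connectivity windows.

Each subject's FC windows (features x total windows, nonnegative) are
factorised as ``V ~ W H`` with nonnegative W (recurring connectivity
patterns) and H (their per-window expression).  The rank is chosen by a
stability criterion: at each candidate rank the factorisation is restarted
from several random initialisations, the basis vectors of every restart pair
are matched by a Hungarian assignment on cosine similarity, and the rank's
stability is the mean matched similarity.  The selected rank is the largest
one whose stability reaches the threshold (random restarts keep finding the
same patterns); the final model is the restart with the lowest reconstruction
error at that rank.  The low-rank reconstruction ``W H`` replaces the raw
windows in all downstream analysis, or the stage can be bypassed entirely
(identity pass-through).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF

from .connectivity import ConnectivityTimeSeries

__all__ = ["NMFModel", "fit_stability_nmf", "reconstruct", "concatenate_windows"]


@dataclass
class NMFModel:
    W: np.ndarray  # (F, r)
    H: np.ndarray  # (r, N)
    rank: int
    stability: dict[int, float] = field(default_factory=dict)
    reconstruction_error: float = 0.0
    seed: int | None = None

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def _cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=0, keepdims=True), 1e-12)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0, keepdims=True), 1e-12)
    return An.T @ Bn


def _matched_similarity(WA: np.ndarray, WB: np.ndarray) -> float:
    """Worst cosine similarity of optimally (Hungarian-)matched basis columns.

    Taking the minimum over matched components rather than the mean makes the
    score discriminative above the true rank: an overcomplete factorisation
    reproduces the real patterns but not the redundant one, and a rank only
    counts as stable if *every* pattern is reproducible across restarts.
    """
    S = _cosine_similarity_matrix(WA, WB)
    rows, cols = linear_sum_assignment(-S)
    return float(S[rows, cols].min())


def fit_stability_nmf(
    V: np.ndarray,
    rank_range=range(1, 7),
    n_restarts: int = 10,
    seed: int | None = None,
    stability_threshold: float = 0.9,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> NMFModel:
    """Fit NMF with stability-based rank selection.

    For each candidate rank, ``n_restarts`` factorisations are run from
    random initialisations; stability is the mean over restart pairs of the
    worst best-match cosine similarity of their basis vectors.  The selected rank is
    the largest candidate with stability >= ``stability_threshold`` (rank 1
    is always perfectly stable, so a model always exists); the returned model
    is the restart with the lowest Frobenius reconstruction error at that
    rank.  Deterministic for a fixed seed.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be nonnegative")
    F, N = V.shape
    ranks = sorted(set(int(r) for r in rank_range))
    if not ranks or ranks[0] < 1 or ranks[-1] > min(F, N):
        raise ValueError(f"rank_range must lie within [1, {min(F, N)}]")
    rng = np.random.default_rng(seed)
    stability: dict[int, float] = {}
    models: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    for r in ranks:
        Ws, Hs, errs = [], [], []
        for _ in range(n_restarts):
            model = NMF(
                n_components=r,
                init="random",
                solver="mu",
                beta_loss="frobenius",
                max_iter=max_iter,
                tol=tol,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            W = model.fit_transform(V)
            Ws.append(W)
            Hs.append(model.components_)
            errs.append(model.reconstruction_err_)
        if r == 1 or n_restarts < 2:
            stability[r] = 1.0
        else:
            sims = [
                _matched_similarity(Ws[i], Ws[j])
                for i in range(n_restarts)
                for j in range(i + 1, n_restarts)
            ]
            stability[r] = float(np.mean(sims))
        best = int(np.argmin(errs))
        models[r] = (Ws[best], Hs[best], float(errs[best]))
    stable = [r for r in ranks if stability[r] >= stability_threshold]
    r_sel = max(stable) if stable else ranks[0]
    W, H, err = models[r_sel]
    return NMFModel(W=W, H=H, rank=r_sel, stability=stability,
                    reconstruction_error=err, seed=seed)


def concatenate_windows(
    series: dict[object, ConnectivityTimeSeries]
) -> tuple[np.ndarray, dict[object, slice]]:
    """Stack all seizures' windows into one (F, N) matrix plus column slices."""
    slices: dict[object, slice] = {}
    cols = []
    start = 0
    for sid, fc in series.items():
        cols.append(fc.features.T)
        slices[sid] = slice(start, start + fc.n_windows)
        start += fc.n_windows
    return np.hstack(cols), slices


def reconstruct(
    model: NMFModel,
    slices: dict[object, slice],
    template: dict[object, ConnectivityTimeSeries],
    renormalize: bool = False,
) -> dict[object, ConnectivityTimeSeries]:
    """Split the low-rank reconstruction back into per-seizure pathways.

    ``template`` supplies per-seizure metadata (channel count, band names,
    window times); window counts are preserved.  ``renormalize`` optionally
    re-applies the per-band L1 normalisation to the reconstructed windows
    (off by default).
    """
    V_hat = model.reconstruction()
    total = V_hat.shape[1]
    if max((sl.stop for sl in slices.values()), default=0) != total or set(
        slices
    ) != set(template):
        raise ValueError("slice bookkeeping does not match the factorised columns")
    out: dict[object, ConnectivityTimeSeries] = {}
    for sid, sl in slices.items():
        tpl = template[sid]
        feats = V_hat[:, sl].T.copy()
        if feats.shape[0] != tpl.n_windows:
            raise ValueError("window count mismatch for seizure %r" % (sid,))
        if renormalize:
            p = tpl.n_pairs
            for b in range(len(tpl.band_names)):
                block = feats[:, b * p : (b + 1) * p]
                tot = block.sum(axis=1, keepdims=True)
                np.divide(block, tot, out=block, where=tot > 0)
        out[sid] = ConnectivityTimeSeries(
            features=feats,
            n_channels=tpl.n_channels,
            band_names=tpl.band_names,
            window_times=tpl.window_times.copy(),
            missing_windows=tpl.missing_windows.copy(),
        )
    return out
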