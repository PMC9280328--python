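"""Time-varying functional connectivity: the seizure "pathway".

Each seizure is summarised as a multivariate time series of band-averaged
coherence values: a 10 s window slides over the seizure in 1 s steps, and in
each window the coherence between every channel pair is computed in six
canonical frequency bands.  Band-averaged coherence sums cross- and
auto-spectra over the in-band frequency bins *before* forming the ratio

    C_ij = |sum_f P_ij(f)|^2 / (sum_f P_ii(f) * sum_f P_jj(f)),

which is bounded in [0, 1] by the Cauchy-Schwarz inequality (it is not the
average of bin-wise coherence).  Spectra come from Welch's method with 2 s
subwindows overlapping by 1 s.  The upper-triangular entries of each band's
coherence matrix are vectorised and L1-normalised per band, so a window of an
n-channel montage carries ``6 * (n^2 - n)/2`` features.

Chronic implants drop signal intermittently; a 10 s window is tolerated as
long as fewer than ``max_missing_subwindows`` of its 2 s Welch subwindows
contain missing samples, in which case spectra are estimated from the clean
subwindows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import SeizureRecording

__all__ = [
    "CANONICAL_BANDS",
    "ConnectivityTimeSeries",
    "band_coherence",
    "coherence_matrices",
    "compute_fc_series",
    "exclude_incomplete_seizures",
    "n_fc_windows",
]

#: Canonical iEEG frequency bands, Hz.  Band membership of an FFT bin is
#: half-open, f1 <= f < f2, so shared printed edges are not double-counted.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
    "high_gamma": (80.0, 150.0),
}


@dataclass
class ConnectivityTimeSeries:
    """Per-window, per-band vectorised coherence features of one seizure.

    ``features`` has shape ``(m, F)`` with ``F = n_bands * (n^2 - n)/2``;
    features are laid out band-block by band-block, channel pairs in
    upper-triangular (row-major) order within each block.
    """

    features: np.ndarray
    n_channels: int
    band_names: tuple[str, ...] = tuple(CANONICAL_BANDS)
    window_times: np.ndarray | None = None  # window start, s from onset
    missing_windows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        m = self.features.shape[0]
        if self.window_times is None:
            self.window_times = np.arange(m, dtype=float)
        if self.missing_windows is None:
            self.missing_windows = np.zeros(m, dtype=bool)
        self.missing_windows = np.asarray(self.missing_windows, dtype=bool)
        expect = len(self.band_names) * self.n_pairs
        if self.features.shape[1] != expect:
            raise ValueError(
                f"feature dimension {self.features.shape[1]} != "
                f"{len(self.band_names)} bands x {self.n_pairs} pairs"
            )

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_channels
        return (n * n - n) // 2

    def band_slice(self, band: int | str) -> slice:
        """Column slice of the features belonging to one band block."""
        if isinstance(band, str):
            band = self.band_names.index(band)
        p = self.n_pairs
        return slice(band * p, (band + 1) * p)

    def band_of_feature(self, j: int) -> str:
        """Band name owning feature column ``j`` (the band-index map)."""
        return self.band_names[j // self.n_pairs]

    def pair_of_feature(self, j: int) -> tuple[int, int]:
        """Channel pair (i, k), i < k, owning feature column ``j``."""
        iu = np.triu_indices(self.n_channels, k=1)
        r = j % self.n_pairs
        return int(iu[0][r]), int(iu[1][r])

    def sliced(self, rows) -> "ConnectivityTimeSeries":
        """New series restricted to the given window rows."""
        return ConnectivityTimeSeries(
            features=self.features[rows].copy(),
            n_channels=self.n_channels,
            band_names=self.band_names,
            window_times=np.atleast_1d(self.window_times[rows]).copy(),
            missing_windows=np.atleast_1d(self.missing_windows[rows]).copy(),
        )


def n_fc_windows(duration_s: float, fc_win_s: float = 10.0, fc_step_s: float = 1.0) -> int:
    """Number of sliding FC windows fitting wholly inside a seizure.

    With the default 10 s window and 1 s step this is ``floor(duration) - 9``.
    """
    return int(np.floor(duration_s) - (fc_win_s - fc_step_s)) if duration_s >= fc_win_s else 0


def _welch_segments(n_samples: int, nperseg: int, noverlap: int) -> np.ndarray:
    step = nperseg - noverlap
    return np.arange(0, n_samples - nperseg + 1, step)


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    f1, f2 = band
    sel = np.flatnonzero((freqs >= f1) & (freqs < f2))
    if sel.size == 0:
        raise ValueError(f"no FFT bins inside band {band}")
    return sel


def _segment_ffts(
    X: np.ndarray, fs: float, nperseg: int, noverlap: int, keep: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Tapered segment FFTs for Welch cross-spectra.

    Returns ``(freqs, Z)`` with ``Z`` of shape (n_segments, n_channels,
    n_freqs).  Segments are mean-detrended and Hamming-tapered; FFT length
    equals the segment length.  ``keep`` optionally selects a subset of the
    Welch segments (used to skip dropout-contaminated subwindows).
    """
    starts = _welch_segments(X.shape[1], nperseg, noverlap)
    if keep is not None:
        starts = starts[keep]
    if starts.size == 0:
        raise ValueError("no usable Welch segments")
    taper = np.hamming(nperseg)
    segs = np.stack([X[:, s : s + nperseg] for s in starts])  # (S, n, T)
    segs = segs - segs.mean(axis=2, keepdims=True)
    Z = np.fft.rfft(segs * taper, axis=2)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, Z


def band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    band: tuple[float, float],
    fs: float,
    welch_win_s: float = 2.0,
    welch_overlap_s: float = 1.0,
) -> float:
    """Band-averaged coherence between two signals over one window."""
    X = np.vstack([x, y]).astype(float)
    C = coherence_matrices(X, fs, bands=[band], welch_win_s=welch_win_s,
                           welch_overlap_s=welch_overlap_s)
    return float(C[0, 0, 1])


def coherence_matrices(
    X: np.ndarray,
    fs: float,
    bands=None,
    welch_win_s: float = 2.0,
    welch_overlap_s: float = 1.0,
    keep_segments: np.ndarray | None = None,
) -> np.ndarray:
    """Band-averaged coherence matrices for one time window.

    Parameters
    ----------
    X:
        ``(n_channels, n_samples)`` window of signal.
    bands:
        Sequence of ``(f1, f2)`` tuples; defaults to the six canonical bands.
    keep_segments:
        Optional boolean mask over the Welch subwindows; ``False`` entries
        are excluded from the spectral averages.

    Returns
    -------
    ``(n_bands, n, n)`` array with unit diagonal, entries in [0, 1].
    """
    if bands is None:
        bands = list(CANONICAL_BANDS.values())
    X = np.atleast_2d(np.asarray(X, dtype=float))
    nperseg = int(round(welch_win_s * fs))
    noverlap = int(round(welch_overlap_s * fs))
    if X.shape[1] < nperseg:
        raise ValueError("window shorter than one Welch subwindow")
    for f1, f2 in bands:
        if f2 > fs / 2:
            raise ValueError(f"band edge {f2} Hz above Nyquist ({fs/2} Hz)")
    freqs, Z = _segment_ffts(X, fs, nperseg, noverlap, keep=keep_segments)
    out = np.empty((len(bands), X.shape[0], X.shape[0]))
    for b, band in enumerate(bands):
        sel = _band_bins(freqs, band)
        Zb = Z[:, :, sel]  # (S, n, nb)
        # cross-spectra averaged over segments, then summed over in-band bins
        P = np.einsum("sif,sjf->ij", Zb, np.conj(Zb)) / Zb.shape[0]
        auto = np.real(np.diag(P))
        denom = np.outer(auto, auto)
        with np.errstate(divide="ignore", invalid="ignore"):
            C = np.abs(P) ** 2 / denom
        C[denom == 0] = 0.0
        np.fill_diagonal(C, 1.0)
        out[b] = np.clip(C, 0.0, 1.0)
    return out


def compute_fc_series(
    rec: SeizureRecording,
    fc_win_s: float = 10.0,
    fc_step_s: float = 1.0,
    bands: dict[str, tuple[float, float]] | None = None,
    welch_win_s: float = 2.0,
    welch_overlap_s: float = 1.0,
    max_missing_subwindows: int | None = 5,
) -> ConnectivityTimeSeries:
    """Sliding-window band coherence features for one seizure.

    Windows start at the seizure onset and advance by ``fc_step_s``; only
    windows lying wholly inside ``[onset, termination)`` are used, giving
    ``floor(duration) - 9`` windows at the defaults.  Seizures shorter than
    one window (10 s) are rejected.  A window is marked missing when at least
    ``max_missing_subwindows`` of its 2 s Welch subwindows contain missing
    samples (``None`` disables the tolerance: any missing subwindow marks the
    window missing); otherwise spectra use the clean subwindows only.

    Each band block of every non-missing window is L1-normalised to sum to 1.
    An all-zero band block is left at zero and the window flagged missing
    rather than divided by zero.
    """
    if bands is None:
        bands = dict(CANONICAL_BANDS)
    if rec.duration_s < fc_win_s:
        raise ValueError(
            f"seizure duration {rec.duration_s:.2f}s below the {fc_win_s:.0f}s minimum"
        )
    keep = rec.included_channels
    n = len(keep)
    n_pairs = (n * n - n) // 2
    band_list = list(bands.values())
    win = int(round(fc_win_s * rec.fs))
    step = int(round(fc_step_s * rec.fs))
    nperseg = int(round(welch_win_s * rec.fs))
    noverlap = int(round(welch_overlap_s * rec.fs))
    m = n_fc_windows(rec.duration_s, fc_win_s, fc_step_s)
    iu = np.triu_indices(n, k=1)
    feats = np.zeros((m, len(band_list) * n_pairs))
    missing = np.zeros(m, dtype=bool)
    times = np.arange(m) * fc_step_s
    anymiss = rec.missing_mask[keep].any(axis=0)
    for w in range(m):
        s0 = rec.onset_sample + w * step
        Xw = rec.data[keep, s0 : s0 + win]
        seg_starts = _welch_segments(win, nperseg, noverlap)
        seg_miss = np.array(
            [anymiss[s0 + s : s0 + s + nperseg].any() for s in seg_starts]
        )
        limit = len(seg_starts) if max_missing_subwindows is None else max_missing_subwindows
        if seg_miss.sum() >= limit or seg_miss.all():
            missing[w] = True
            continue
        C = coherence_matrices(
            Xw, rec.fs, bands=band_list, welch_win_s=welch_win_s,
            welch_overlap_s=welch_overlap_s,
            keep_segments=~seg_miss if seg_miss.any() else None,
        )
        for b in range(len(band_list)):
            v = C[b][iu]
            tot = v.sum()
            if tot == 0:
                missing[w] = True
            else:
                v = v / tot
            feats[w, b * n_pairs : (b + 1) * n_pairs] = v
    return ConnectivityTimeSeries(
        features=feats,
        n_channels=n,
        band_names=tuple(bands),
        window_times=times,
        missing_windows=missing,
    )


def exclude_incomplete_seizures(
    series: dict[object, ConnectivityTimeSeries],
) -> tuple[dict[object, ConnectivityTimeSeries], list[object]]:
    """Drop seizures whose FC series contains any missing window.

    Returns the retained series (insertion order preserved) and the list of
    excluded seizure ids.
    """
    keep: dict[object, ConnectivityTimeSeries] = {}
    excluded: list[object] = []
    for sid, fc in series.items():
        if fc.missing_windows.any():
            excluded.append(sid)
        else:
            keep[sid] = fc
    return keep, excluded
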