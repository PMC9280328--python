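"""Preprocessing of raw seizure iEEG clips.

Pipeline stages: downsampling a cohort to a common rate, linear interpolation
of short missing segments, common average referencing, zero-phase Butterworth
band-pass plus mains notch filtering, and line-length based detection of
signal dropouts (flat telemetry segments) in chronically recorded data.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal

from .recording import SeizureRecording

__all__ = [
    "line_length",
    "detect_dropout_windows",
    "interpolate_short_gaps",
    "common_average_reference",
    "filter_recording",
    "resample_to_common",
]


def line_length(x: np.ndarray) -> float:
    """Mean absolute first difference of a 1-D signal.

    ``L = (1/(T-1)) * sum_i |x_{i+1} - x_i|``.  Near zero for flat (dropout)
    segments, which makes it a cheap detector of missing telemetry.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("line_length needs a 1-D vector with at least 2 samples")
    return float(np.abs(np.diff(x)).mean())


def detect_dropout_windows(
    rec: SeizureRecording,
    win_s: float = 0.1,
    step_s: float = 0.05,
    ll_thresh: float = 0.5,
    min_flat_channels: int | None = None,
) -> np.ndarray:
    """Flag samples lying in flat (dropout) windows.

    Line length is computed per channel in sliding windows (``win_s`` long,
    advancing by ``step_s``).  A window where at least ``min_flat_channels``
    channels have line length <= ``ll_thresh`` is flagged, together with the
    windows immediately before and after it.  ``min_flat_channels`` defaults
    to half the montage, ``ceil(n/2)`` (8 of 16 on a 16-channel implant).

    Returns a boolean ``(n_channels, n_samples)`` mask (``True`` = missing);
    flagged windows apply to every channel.
    """
    n = len(rec.included_channels)
    if min_flat_channels is None:
        min_flat_channels = math.ceil(n / 2)
    win = int(round(win_s * rec.fs))
    step = int(round(step_s * rec.fs))
    if win < 2 or rec.n_samples < win:
        raise ValueError("recording shorter than one dropout-detection window")
    starts = np.arange(0, rec.n_samples - win + 1, step)
    data = rec.data[rec.included_channels]
    flat_counts = np.empty(len(starts), dtype=int)
    for k, s0 in enumerate(starts):
        seg = data[:, s0 : s0 + win]
        ll = np.abs(np.diff(seg, axis=1)).mean(axis=1)
        flat_counts[k] = int((ll <= ll_thresh).sum())
    flagged = flat_counts >= min_flat_channels
    # neighbouring windows on either side of a flat window are also unusable
    padded = flagged.copy()
    padded[:-1] |= flagged[1:]
    padded[1:] |= flagged[:-1]
    mask = np.zeros(rec.data.shape, dtype=bool)
    for k, s0 in enumerate(starts):
        if padded[k]:
            mask[:, s0 : s0 + win] = True
    return mask


def _gap_runs(mask_row: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask_row.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def interpolate_short_gaps(
    rec: SeizureRecording, max_gap_s: float = 0.05
) -> SeizureRecording:
    """Linearly interpolate missing segments shorter than ``max_gap_s``.

    Each channel is treated independently.  Filled samples are unmasked;
    longer gaps and gaps touching the clip edges (no anchor on one side)
    are left untouched.
    """
    out = rec.copy_with()
    max_len = max_gap_s * rec.fs
    for ch in range(rec.n_channels):
        for start, stop in _gap_runs(out.missing_mask[ch]):
            if (stop - start) >= max_len:
                continue
            if start == 0 or stop == rec.n_samples:
                continue  # would require extrapolation
            x0, x1 = out.data[ch, start - 1], out.data[ch, stop]
            t = np.arange(1, stop - start + 1) / (stop - start + 1)
            out.data[ch, start:stop] = x0 + t * (x1 - x0)
            out.missing_mask[ch, start:stop] = False
    return out


def common_average_reference(rec: SeizureRecording) -> SeizureRecording:
    """Subtract the instantaneous mean over non-excluded channels.

    Idempotent; the per-sample mean across referenced channels is zero
    afterwards.  Requires at least two non-excluded channels.
    """
    keep = rec.included_channels
    if len(keep) < 2:
        raise ValueError("common average reference needs at least 2 channels")
    out = rec.copy_with()
    out.data[keep] -= out.data[keep].mean(axis=0, keepdims=True)
    return out


def filter_recording(
    rec: SeizureRecording,
    band: tuple[float, float] = (1.0, 150.0),
    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0),
    notch_width: float = 2.0,
    order: int = 4,
) -> SeizureRecording:
    """Zero-phase Butterworth band-pass plus mains notch filtering.

    A filter of the stated ``order`` is designed and applied forward-backward
    (``filtfilt``), i.e. the magnitude response is effectively squared.  Each
    notch is a Butterworth band-stop of total width ``notch_width`` centred on
    a mains harmonic; harmonics at or above the Nyquist rate are skipped.
    """
    lo, hi = band
    if rec.fs <= 2 * hi:
        raise ValueError(f"sampling rate {rec.fs} Hz too low for band edge {hi} Hz")
    out = rec.copy_with()
    keep = rec.included_channels
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out.data[keep] = signal.sosfiltfilt(sos, out.data[keep], axis=1)
    for f0 in notch_freqs:
        edges = (f0 - notch_width / 2, f0 + notch_width / 2)
        if edges[1] >= rec.fs / 2:
            continue
        sos = signal.butter(order, edges, btype="bandstop", fs=rec.fs, output="sos")
        out.data[keep] = signal.sosfiltfilt(sos, out.data[keep], axis=1)
    return out


def resample_to_common(recordings: list[SeizureRecording]) -> list[SeizureRecording]:
    """Downsample every recording to the lowest sampling rate in the cohort.

    Uses polyphase resampling (anti-aliasing built in).  Marker samples and
    the missing mask are mapped onto the new sample grid.
    """
    if not recordings:
        return []
    fs_min = min(r.fs for r in recordings)
    out = []
    for rec in recordings:
        if rec.fs == fs_min:
            out.append(rec.copy_with())
            continue
        frac = _as_fraction(fs_min / rec.fs)
        up, down = frac
        data = signal.resample_poly(rec.data, up, down, axis=1)
        ratio = fs_min / rec.fs
        n_new = data.shape[1]
        # a new sample is missing if any source sample it covers was missing
        mask = np.zeros((rec.n_channels, n_new), dtype=bool)
        miss_cols = np.flatnonzero(rec.missing_mask.any(axis=0))
        if miss_cols.size:
            new_cols = np.unique(np.floor(miss_cols * ratio).astype(int))
            new_cols = new_cols[new_cols < n_new]
            for ch in range(rec.n_channels):
                src = np.flatnonzero(rec.missing_mask[ch])
                cols = np.unique(np.floor(src * ratio).astype(int))
                mask[ch, cols[cols < n_new]] = True
        out.append(
            rec.copy_with(
                data=data,
                fs=fs_min,
                onset_sample=int(round(rec.onset_sample * ratio)),
                termination_sample=int(round(rec.termination_sample * ratio)),
                missing_mask=mask,
            )
        )
    return out


def _as_fraction(x: float, max_den: int = 1000) -> tuple[int, int]:
    from fractions import Fraction

    fr = Fraction(x).limit_denominator(max_den)
    return fr.numerator, fr.denominator
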