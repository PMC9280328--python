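"""Raw iEEG seizure clips.

A :class:`SeizureRecording` holds a multichannel voltage matrix together with
its sampling rate, electrographic onset/termination markers, a per-sample
missing-data mask and an optional list of excluded (noisy) channels.  The
exclusion list is an input: noisy channels are identified upstream (e.g. by
visual review) and are never touched by the numerical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SeizureRecording"]


@dataclass
class SeizureRecording:
    """Multichannel iEEG clip containing one seizure.

    Parameters
    ----------
    data:
        Voltage matrix, shape ``(n_channels, n_samples)``.
    fs:
        Sampling rate in Hz.
    onset_sample, termination_sample:
        Electrographic seizure markers (sample indices, half-open
        ``[onset, termination)``).  Default to the clip boundaries.
    missing_mask:
        Boolean matrix of the same shape as ``data``; ``True`` marks samples
        that are missing (dropouts, artefact-removed segments).
    channel_labels:
        Optional channel names; defaults to ``ch00, ch01, ...``.
    excluded_channels:
        Indices of channels excluded from analysis (noisy electrodes).
    """

    data: np.ndarray
    fs: float
    onset_sample: int = 0
    termination_sample: int | None = None
    missing_mask: np.ndarray | None = None
    channel_labels: list[str] | None = None
    excluded_channels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.termination_sample is None:
            self.termination_sample = self.data.shape[1]
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.data.shape:
                raise ValueError("missing_mask shape must match data")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if not self.termination_sample > self.onset_sample:
            raise ValueError("termination must come after onset")
        self.excluded_channels = frozenset(int(c) for c in self.excluded_channels)
        if any(c < 0 or c >= self.n_channels for c in self.excluded_channels):
            raise ValueError("excluded channel index out of range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        """Seizure duration in seconds, (termination - onset) / fs."""
        return (self.termination_sample - self.onset_sample) / self.fs

    @property
    def included_channels(self) -> np.ndarray:
        """Sorted indices of channels that are not excluded."""
        return np.array(
            [c for c in range(self.n_channels) if c not in self.excluded_channels],
            dtype=int,
        )

    def copy_with(self, **changes) -> "SeizureRecording":
        """Return a copy with ``data``/``missing_mask`` copied and fields replaced."""
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "missing_mask" not in changes:
            out.missing_mask = self.missing_mask.copy()
        return out
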