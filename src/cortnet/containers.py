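"""In-memory containers shared across the pipeline.

A :class:`Recording` is a multichannel scalp-EEG segment store: one
contiguous ``channels x samples`` array in microvolts plus a list of
half-open sample ranges marking the continuous stretches of data.  The
segment list exists because N2-sleep epochs are discontinuous excerpts of a
longer recording and because spindle excision cuts the timeline: no filter,
Hilbert transform or windowed statistic may ever run across a cut, so every
stage iterates segments independently.

:class:`ParcelSignals` is the analogous container after inverse modelling
and parcel collapse: ``n_parcels x samples`` source-space signals for one
frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Recording", "ParcelSignals", "check_segments"]


def check_segments(segments: Sequence[tuple[int, int]], n_samples: int) -> list[tuple[int, int]]:
    """Validate half-open, sorted, non-overlapping segment bounds."""
    segs = [(int(a), int(b)) for a, b in segments]
    prev_end = 0
    for a, b in segs:
        if not (0 <= a < b <= n_samples):
            raise ValueError(f"segment ({a}, {b}) outside record of {n_samples} samples")
        if a < prev_end:
            raise ValueError("segments overlap or are unsorted")
        prev_end = b
    return segs


@dataclass
class Recording:
    """Multichannel EEG data with montage and segment structure.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels.
    positions : ndarray, shape (n_channels, 3), optional
        Electrode positions, normalized to the unit sphere.
    reference : str
        Reference tag, e.g. ``"AFz"`` or ``"average"``.
    bads : list of str
        Channels flagged as bad (no contact); interpolated in preprocessing.
    segments : list of (int, int)
        Half-open sample ranges of continuous data.  Defaults to one segment
        spanning the whole array.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    positions: np.ndarray | None = None
    reference: str = "unknown"
    bads: list[str] = field(default_factory=list)
    segments: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match data rows")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[0], 3):
                raise ValueError("positions must be (n_channels, 3)")
            norms = np.linalg.norm(self.positions, axis=1)
            if np.any(norms <= 0):
                raise ValueError("electrode positions must be nonzero")
            self.positions = self.positions / norms[:, None]
        if not self.segments:
            self.segments = [(0, self.data.shape[1])]
        self.segments = check_segments(self.segments, self.data.shape[1])
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        """Total duration of data inside segments, in seconds."""
        return sum(b - a for a, b in self.segments) / self.fs

    def iter_segments(self) -> Iterator[tuple[tuple[int, int], np.ndarray]]:
        for a, b in self.segments:
            yield (a, b), self.data[:, a:b]

    def copy(self, **changes) -> "Recording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "segments" not in changes:
            out.segments = list(self.segments)
        return out


@dataclass
class ParcelSignals:
    """Band-specific parcel time courses after source collapse."""

    data: np.ndarray  # (n_parcels, n_samples)
    fs: float
    band_fc: float | None = None
    segments: list[tuple[int, int]] = field(default_factory=list)
    parcel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (parcels x samples)")
        if not self.segments:
            self.segments = [(0, self.data.shape[1])]
        self.segments = check_segments(self.segments, self.data.shape[1])

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def iter_segments(self) -> Iterator[tuple[tuple[int, int], np.ndarray]]:
        for a, b in self.segments:
            yield (a, b), self.data[:, a:b]
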