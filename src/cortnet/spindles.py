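"""Sleep-spindle detection, cross-channel gating, grouping, and removal.

Spindles (transient 11-15 Hz waxing-waning bursts, the hallmark of N2
sleep) are detected per channel with an amplitude-envelope detector: the
channel is band-passed to the spindle band, the Hilbert envelope is
smoothed, and events are flagged where the envelope exceeds ``k_upper``
times its channel mean, extended to where it falls back below ``k_lower``
times the mean, and kept when the duration lies in [0.5, 3] s.

To limit false positives, candidate segments are then gated by the *summed*
spindle-band power envelope over all channels: a candidate survives only if
that summed envelope, within the segment, exceeds ``theta`` times the mean
of the per-event peak amplitudes of the summed envelope (computed per
recording).

Removal excises the gated intervals (plus padding) and re-segments the
recording at the cuts, so downstream filtering and windowing never span a
cut — excision, not zeroing.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.signal import hilbert

from .containers import Recording

__all__ = [
    "SpindleDetectorParams",
    "SpindleAnnotations",
    "SpindleGroupMetrics",
    "spindle_band_filter",
    "detect_spindles_channel",
    "detect_spindles",
    "gate_by_global_power",
    "group_spindles",
    "remove_spindles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpindleDetectorParams:
    band: tuple[float, float] = (11.0, 15.0)
    k_upper: float = 3.0
    k_lower: float = 1.5
    min_dur_s: float = 0.5
    max_dur_s: float = 3.0
    smooth_s: float = 0.1  # short enough not to stretch sub-0.5 s bursts past the gate
    theta: float = 0.5  # global-power gate factor
    gap_s: float = 1.0  # grouping gap


@dataclass
class SpindleAnnotations:
    """Per-channel detections plus gated global spindle intervals (seconds)."""

    channel_intervals: dict[str, list[tuple[float, float]]]
    global_intervals: list[tuple[float, float]]
    peak_power: list[float]
    params: dict
    duration_s: float

    def __post_init__(self) -> None:
        for a, b in self.global_intervals:
            if not 0 <= a < b <= self.duration_s + 1e-9:
                raise ValueError(f"interval ({a}, {b}) outside record")

    @property
    def n_spindles(self) -> int:
        return len(self.global_intervals)


@dataclass
class SpindleGroupMetrics:
    spindles_per_min: float
    groups_per_min: float
    group_duration_mean_s: float
    group_duration_sd_s: float
    spindles_per_group_mean: float
    spindles_per_group_sd: float
    group_spans: list[tuple[float, float]] = field(default_factory=list)


def _merge_intervals(
    intervals: list[tuple[float, float]], gap: float = 0.0
) -> list[tuple[float, float]]:
    if not intervals:
        return []
    out = []
    for a, b in sorted(intervals):
        if out and a - out[-1][1] <= gap:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def spindle_band_filter(
    data: np.ndarray,
    fs: float,
    band: tuple[float, float] = (11.0, 15.0),
    segments: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Zero-phase Kaiser FIR band-pass to the spindle band, per segment."""
    lo, hi = band
    width = 2.0 / (fs / 2.0)
    numtaps, beta = sps.kaiserord(45.0, width)
    numtaps |= 1
    taps = sps.firwin(numtaps, [lo - 1.0, hi + 1.0], window=("kaiser", beta), pass_zero=False, fs=fs)
    one_d = data.ndim == 1
    x = data[None, :] if one_d else data
    out = np.zeros_like(x, dtype=float)
    for a, b in segments or [(0, x.shape[1])]:
        out[:, a:b] = sps.fftconvolve(x[:, a:b], taps[None, :], mode="same", axes=1)
    return out[0] if one_d else out


def _smooth_envelope(
    x: np.ndarray, fs: float, smooth_s: float, segments: list[tuple[int, int]] | None
) -> np.ndarray:
    env = np.zeros_like(x, dtype=float)
    win = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(win) / win
    for a, b in segments or [(0, x.size)]:
        e = np.abs(hilbert(x[a:b]))
        env[a:b] = np.convolve(e, kernel, mode="same")
    return env


def detect_spindles_channel(
    x: np.ndarray,
    fs: float,
    params: SpindleDetectorParams = SpindleDetectorParams(),
    segments: list[tuple[int, int]] | None = None,
    prefiltered: bool = False,
) -> list[tuple[int, int]]:
    """Envelope-threshold spindle detection on one channel.

    Returns half-open sample intervals (the lower-threshold extension);
    the [0.5, 3] s duration gate applies to that extended interval.  The
    channel-mean envelope is the adaptive baseline, so the record must be
    at least 30 s long.
    """
    x = np.asarray(x, float)
    if x.size < 30 * fs:
        raise ValueError("record shorter than 30 s: envelope baseline unstable")
    xb = x if prefiltered else spindle_band_filter(x, fs, params.band, segments)
    env = _smooth_envelope(xb, fs, params.smooth_s, segments)
    mean_env = env.mean()
    if mean_env == 0:
        return []
    hi, lo = params.k_upper * mean_env, params.k_lower * mean_env
    above_hi = env >= hi
    above_lo = env >= lo
    events: list[tuple[int, int]] = []
    for a, b in segments or [(0, x.size)]:
        seg_hi = above_hi[a:b]
        if not seg_hi.any():
            continue
        seg_lo = above_lo[a:b]
        # runs of the lower threshold that contain at least one upper crossing
        edges = np.diff(np.concatenate([[0], seg_lo.astype(int), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if not seg_hi[s:e].any():
                continue
            dur = (e - s) / fs
            if params.min_dur_s <= dur <= params.max_dur_s:
                events.append((a + int(s), a + int(e)))
    return events


def detect_spindles(
    rec: Recording, params: SpindleDetectorParams = SpindleDetectorParams()
) -> SpindleAnnotations:
    """Per-channel detection followed by the cross-channel power gate."""
    band_sig = spindle_band_filter(rec.data, rec.fs, params.band, rec.segments)
    detections = {
        name: detect_spindles_channel(
            band_sig[i], rec.fs, params, rec.segments, prefiltered=True
        )
        for i, name in enumerate(rec.ch_names)
    }
    return gate_by_global_power(detections, band_sig, rec.fs, params, rec.segments)


def gate_by_global_power(
    detections: dict[str, list[tuple[int, int]]],
    band_signals: np.ndarray,
    fs: float,
    params: SpindleDetectorParams = SpindleDetectorParams(),
    segments: list[tuple[int, int]] | None = None,
) -> SpindleAnnotations:
    """Keep candidates whose summed cross-channel spindle power is high enough.

    The summed power envelope is the channel-sum of squared smoothed
    envelopes; the threshold is ``theta`` times the mean of per-candidate
    peak amplitudes of that envelope (computed once per recording).
    """
    n_samples = band_signals.shape[1]
    power = np.zeros(n_samples)
    for ch in range(band_signals.shape[0]):
        env = _smooth_envelope(band_signals[ch], fs, params.smooth_s, segments)
        power += env**2
    candidates = _merge_intervals(
        [iv for ivs in detections.values() for iv in ivs], gap=0.0
    )
    peaks = [float(power[a:b].max()) for a, b in candidates]
    if peaks:
        threshold = params.theta * float(np.mean(peaks))
        kept = [(iv, p) for iv, p in zip(candidates, peaks) if p >= threshold]
    else:
        kept = []
    return SpindleAnnotations(
        channel_intervals={
            ch: [(a / fs, b / fs) for a, b in ivs] for ch, ivs in detections.items()
        },
        global_intervals=[(a / fs, b / fs) for (a, b), _ in kept],
        peak_power=[p for _, p in kept],
        params=asdict(params),
        duration_s=n_samples / fs,
    )


def group_spindles(ann: SpindleAnnotations, gap_s: float | None = None) -> SpindleGroupMetrics:
    """Merge gated spindles whose gaps are <= gap_s into spindle groups.

    ``spindles_per_group`` counts the *channel-level* detections whose
    intervals overlap the group span (a spindle seen on 15 channels
    contributes 15).
    """
    if gap_s is None:
        gap_s = ann.params.get("gap_s", 1.0)
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    minutes = ann.duration_s / 60.0
    groups = _merge_intervals(ann.global_intervals, gap=gap_s)
    chan_ivs = [iv for ivs in ann.channel_intervals.values() for iv in ivs]
    counts = [
        sum(1 for a, b in chan_ivs if a < g1 and g0 < b) for g0, g1 in groups
    ]
    durations = [g1 - g0 for g0, g1 in groups]
    return SpindleGroupMetrics(
        spindles_per_min=len(ann.global_intervals) / minutes if minutes else 0.0,
        groups_per_min=len(groups) / minutes if minutes else 0.0,
        group_duration_mean_s=float(np.mean(durations)) if durations else 0.0,
        group_duration_sd_s=float(np.std(durations)) if durations else 0.0,
        spindles_per_group_mean=float(np.mean(counts)) if counts else 0.0,
        spindles_per_group_sd=float(np.std(counts)) if counts else 0.0,
        group_spans=groups,
    )


def remove_spindles(rec: Recording, ann: SpindleAnnotations, pad_s: float = 0.25) -> Recording:
    """Excise gated spindle intervals (padded) and re-segment at the cuts."""
    if abs(ann.duration_s - rec.n_samples / rec.fs) > 1.0 / rec.fs + 1e-9:
        raise ValueError("annotations do not match this recording's timeline")
    if not ann.global_intervals:
        return rec.copy()
    cuts = _merge_intervals(
        [(max(a - pad_s, 0.0), min(b + pad_s, ann.duration_s)) for a, b in ann.global_intervals]
    )
    # half-up rounding keeps excised lengths exact (round() ties-to-even
    # would drop a sample whenever both edges land on .5)
    def _sample(x: float) -> int:
        return int(np.floor(x * rec.fs + 0.5))

    cut_samples = [(_sample(a), _sample(b)) for a, b in cuts]
    pieces, segments, pos = [], [], 0
    for a, b in rec.segments:
        keep_start = a
        bounds = []
        for ca, cb in cut_samples:
            ca, cb = max(ca, a), min(cb, b)
            if cb <= ca:
                continue
            if ca > keep_start:
                bounds.append((keep_start, ca))
            keep_start = cb
        if keep_start < b:
            bounds.append((keep_start, b))
        for s, e in bounds:
            pieces.append(rec.data[:, s:e])
            segments.append((pos, pos + (e - s)))
            pos += e - s
    if not pieces:
        raise ValueError("spindle removal excised the entire recording")
    out = rec.copy(data=np.concatenate(pieces, axis=1), segments=segments)
    if out.n_samples / out.fs < 180.0:
        logger.warning("less than 3 minutes of data remain after spindle removal")
        out.meta = dict(out.meta, short_n2=True)
    return out
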