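"""Spindle detector, cross-channel gate, grouping metrics, and excision."""

import numpy as np
import pytest

from cortnet.containers import Recording
from cortnet.spindles import (
    SpindleAnnotations,
    SpindleDetectorParams,
    detect_spindles,
    detect_spindles_channel,
    gate_by_global_power,
    group_spindles,
    remove_spindles,
    spindle_band_filter,
)
from cortnet.synth import SpindleSpec, inject_spindles, simulate_parcel_sources

FS = 250.0


def _spindle_recording(n_ch=8, duration=300.0, rate=5.0, amplitude=3.0, seed=0):
    X = simulate_parcel_sources([], n_ch, FS, duration, seed=seed)
    out, truth = inject_spindles(
        X, SpindleSpec(rate_per_min=rate, amplitude_rel=amplitude), FS, seed=seed + 1
    )
    rec = Recording(data=out, fs=FS, ch_names=[f"c{i}" for i in range(n_ch)])
    return rec, truth


def _match(intervals, truth, fs=FS, tol_s=0.3):
    """Count truth events hit by a detection (midpoint containment, padded)."""
    hits = 0
    for ev in truth:
        mid = 0.5 * (ev.start + ev.end) / fs
        if any(a - tol_s <= mid <= b + tol_s for a, b in intervals):
            hits += 1
    return hits


class TestChannelDetector:
    def test_noise_without_bursts_yields_nothing(self):
        x = 0.01 * np.random.default_rng(0).standard_normal(int(60 * FS))
        # scale-free detector: use a burst-free record, adaptive threshold
        events = detect_spindles_channel(x, FS)
        assert events == [] or len(events) <= 2  # rare envelope flukes only

    def test_recall_and_precision_on_truth(self):
        rec, truth = _spindle_recording(n_ch=1, duration=600.0)
        events = detect_spindles_channel(rec.data[0], FS)
        intervals = [(a / FS, b / FS) for a, b in events]
        recall = _match(intervals, truth) / len(truth)
        # precision: every detection overlaps a truth event
        true_spans = [(e.start / FS - 0.3, e.end / FS + 0.3) for e in truth]
        prec_hits = sum(
            1 for a, b in intervals if any(ta < b and a < tb for ta, tb in true_spans)
        )
        assert recall >= 0.9
        assert prec_hits / max(len(intervals), 1) >= 0.9

    def test_short_burst_rejected_by_duration_gate(self):
        """A 0.3 s burst at spindle-typical amplitude stays below 0.5 s."""
        x = simulate_parcel_sources([], 1, FS, 60, seed=1)[0]
        rms = np.sqrt(np.mean(x**2))
        t = np.arange(int(0.3 * FS)) / FS
        burst = 3 * rms * np.hanning(t.size) * np.sin(2 * np.pi * 13 * t)
        x[5000: 5000 + burst.size] += burst
        events = detect_spindles_channel(x, FS)
        assert all(not (4900 < a < 5200) for a, _ in events)

    def test_record_too_short_raises(self):
        with pytest.raises(ValueError, match="30 s"):
            detect_spindles_channel(np.zeros(int(10 * FS)), FS)

    def test_translation_equivariance(self):
        """Shifting the record by whole samples shifts detections exactly."""
        rec, _ = _spindle_recording(n_ch=1, duration=120.0, seed=5)
        x = rec.data[0]
        shift = 500
        events = detect_spindles_channel(x[: -shift], FS)
        shifted = detect_spindles_channel(
            np.concatenate([x[-shift:], x[: -shift]])[shift + len(x) - len(x):], FS
        ) if False else detect_spindles_channel(x[shift: len(x)], FS)
        # compare events well inside both records
        base = [(a, b) for a, b in events if a > 2000 and b < len(x) - shift - 2000]
        moved = [(a + shift, b + shift) for a, b in shifted if a > 1500]
        for a, b in base[:5]:
            assert any(abs(a - ma) <= 25 for ma, _ in moved)


class TestGlobalPowerGate:
    def test_widespread_burst_retained_lone_channel_rejected(self):
        n_ch = 20
        X = simulate_parcel_sources([], n_ch, FS, 300, seed=2)
        wide = np.ones(n_ch)
        lone = np.zeros(n_ch)
        lone[0] = 1.0
        out, truth = inject_spindles(
            X,
            [
                SpindleSpec(rate_per_min=2.0, amplitude_rel=4.0, channels=wide),
                SpindleSpec(rate_per_min=2.0, amplitude_rel=1.2, channels=lone),
            ],
            FS,
            seed=3,
        )
        rec = Recording(data=out, fs=FS, ch_names=[f"c{i}" for i in range(n_ch)])
        ann = detect_spindles(rec, SpindleDetectorParams(theta=0.5))
        wide_truth = [e for e in truth if e.profile == 0]
        lone_truth = [e for e in truth if e.profile == 1]
        assert _match(ann.global_intervals, wide_truth) / len(wide_truth) >= 0.8
        # weak single-channel candidates lack cross-channel support
        assert _match(ann.global_intervals, lone_truth) <= 0.5 * len(lone_truth)

    def test_theta_zero_disables_gate(self):
        rec, _ = _spindle_recording(duration=120.0, seed=4)
        band = spindle_band_filter(rec.data, FS)
        dets = {
            name: detect_spindles_channel(band[i], FS, prefiltered=True)
            for i, name in enumerate(rec.ch_names)
        }
        ann = gate_by_global_power(dets, band, FS, SpindleDetectorParams(theta=0.0))
        n_candidates = len(
            gate_by_global_power(dets, band, FS, SpindleDetectorParams(theta=0.0)).global_intervals
        )
        merged_candidates = ann.global_intervals
        assert len(merged_candidates) == n_candidates  # all retained

    def test_no_candidates_is_empty_not_error(self):
        band = 0.01 * np.random.default_rng(0).standard_normal((4, int(60 * FS)))
        ann = gate_by_global_power({"c0": []}, band, FS)
        assert ann.global_intervals == []

    def test_gating_never_invents_intervals(self):
        rec, _ = _spindle_recording(duration=120.0, seed=6)
        ann = detect_spindles(rec)
        chan_union = sorted(
            iv for ivs in ann.channel_intervals.values() for iv in ivs
        )
        for a, b in ann.global_intervals:
            assert any(ca <= a and b <= cb + 1e-9 or (ca < b and a < cb) for ca, cb in chan_union)


class TestGrouping:
    def _ann(self, intervals, channel=None, duration=60.0):
        return SpindleAnnotations(
            channel_intervals={"c0": channel if channel is not None else list(intervals)},
            global_intervals=list(intervals),
            peak_power=[1.0] * len(intervals),
            params={"gap_s": 1.0},
            duration_s=duration,
        )

    def test_separated_events_make_singleton_groups(self):
        m = group_spindles(self._ann([(0.0, 1.0), (5.0, 6.0)]), gap_s=0.5)
        assert m.groups_per_min == pytest.approx(2.0)
        assert m.spindles_per_group_mean == 1.0

    def test_merge_arithmetic(self):
        m = group_spindles(self._ann([(0.0, 1.0), (1.2, 2.2)]), gap_s=0.5)
        assert len(m.group_spans) == 1
        assert m.group_duration_mean_s == pytest.approx(2.2)

    def test_spindles_per_group_counts_channel_detections(self):
        """15 co-detected channels in one group span count as 15."""
        chan = [(1.0, 2.0)] * 1  # container per channel below
        ann = SpindleAnnotations(
            channel_intervals={f"c{i}": [(1.0, 2.0)] for i in range(15)},
            global_intervals=[(1.0, 2.0)],
            peak_power=[1.0],
            params={"gap_s": 1.0},
            duration_s=60.0,
        )
        m = group_spindles(ann, gap_s=1.0)
        assert m.spindles_per_group_mean == pytest.approx(15.0)

    def test_rate_invariants(self):
        m = group_spindles(self._ann([(0.0, 1.0), (1.1, 2.1), (10.0, 11.0)]), gap_s=0.5)
        assert m.groups_per_min <= m.spindles_per_min


class TestRemoval:
    def test_empty_annotations_identity(self):
        rec, _ = _spindle_recording(duration=120.0, seed=7)
        ann = SpindleAnnotations(
            channel_intervals={}, global_intervals=[], peak_power=[],
            params={}, duration_s=rec.n_samples / FS,
        )
        out = remove_spindles(rec, ann)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_excision_arithmetic_with_padding(self):
        rec, _ = _spindle_recording(duration=200.0, seed=8)
        ann = SpindleAnnotations(
            channel_intervals={}, global_intervals=[(50.0, 51.0)], peak_power=[1.0],
            params={}, duration_s=rec.n_samples / FS,
        )
        out = remove_spindles(rec, ann, pad_s=0.25)
        assert out.n_samples == rec.n_samples - int(1.5 * FS)
        assert len(out.segments) == 2  # a cut was inserted

    def test_removal_warns_when_under_three_minutes(self):
        rec, _ = _spindle_recording(duration=200.0, seed=9)
        ann = SpindleAnnotations(
            channel_intervals={}, global_intervals=[(5.0, 190.0)], peak_power=[1.0],
            params={}, duration_s=rec.n_samples / FS,
        )
        out = remove_spindles(rec, ann)
        assert out.meta.get("short_n2") is True

    def test_mismatched_timeline_rejected(self):
        rec, _ = _spindle_recording(duration=120.0, seed=10)
        ann = SpindleAnnotations(
            channel_intervals={}, global_intervals=[], peak_power=[],
            params={}, duration_s=500.0,
        )
        with pytest.raises(ValueError, match="timeline"):
            remove_spindles(rec, ann)

    def test_removing_zero_amplitude_spindles_preserves_connectivity(self):
        """Excising marked intervals that carry no burst energy leaves the
        dwPLI of a coupled pair essentially unchanged."""
        from scipy.signal import hilbert

        from cortnet.connectivity import dwpli
        from cortnet.synth import CouplingSpec

        spec = [CouplingSpec(pair=(0, 1), mode="phase", band_hz=10.0, kappa=100.0)]
        X = simulate_parcel_sources(spec, 3, FS, 300, seed=11, background_mix=0.05)
        rec = Recording(data=X, fs=FS, ch_names=["a", "b", "c"])
        ann = SpindleAnnotations(
            channel_intervals={}, global_intervals=[(40.0, 41.0), (100.0, 101.5)],
            peak_power=[1.0, 1.0], params={}, duration_s=rec.n_samples / FS,
        )
        out = remove_spindles(rec, ann)

        def pair_dwpli(r):
            z = np.vstack([hilbert(r.data[i]) for i in (0, 1)])
            return dwpli(z[0], z[1], FS, segments=r.segments)

        assert pair_dwpli(out) == pytest.approx(pair_dwpli(rec), abs=0.02)
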