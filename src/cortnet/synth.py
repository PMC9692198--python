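"""Synthetic N2-sleep EEG with known ground truth.

This module generates everything the pipeline consumes — parcel-level source
signals with controllable amplitude-envelope correlation and phase-lag
coupling, waxing-waning sleep-spindle bursts, sensor projections through a
lead field, and whole cohorts with group structure — so that every
downstream stage (filtering, inverse modelling, connectivity estimation,
edge pruning, group statistics) can be tested against exact ground truth
without any clinical data.

Signal model
------------
Uncoupled parcels carry 1/f^slope background noise with a 10-14 Hz resting
bump.  An envelope-coupled pair shares a slow (0.1-0.5 Hz) log-normal
amplitude modulator: each member's envelope is ``exp(sigma * x_i)`` where
``x_i = alpha*s0 + sqrt(1-alpha^2)*s_i`` mixes a shared and an individual
slow Gaussian.  Because the envelopes are jointly log-normal, the Pearson
correlation of the envelopes is an exact function of ``alpha`` and is
inverted analytically so the *target* correlation is realized, not merely
approached.  A phase-coupled pair shares one constant-modulus narrow-band
oscillator; the second member is rotated by a fixed lag plus slow von-Mises
phase jitter of concentration ``kappa``.

All generation is a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import Recording

__all__ = [
    "CouplingSpec",
    "SpindleSpec",
    "SpindleEvent",
    "CohortSpec",
    "simulate_parcel_sources",
    "inject_spindles",
    "project_to_sensors",
    "generate_cohort",
    "simulate_cohort_matrices",
    "background_noise",
    "narrowband_carrier",
]

_SYNDROMES = ("self-limited", "West", "unclassified focal", "other")
_NEURO = ("Typical", "Mild", "Severe")


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling between one parcel pair.

    ``strength`` is the target envelope Pearson correlation for
    ``mode="envelope"``; for ``mode="phase"`` the coupling is described by
    ``lag_rad`` (mean phase difference) and ``kappa`` (von-Mises
    concentration of the jitter around that lag).  Envelope-coupled members
    ride a *shared* carrier offset by ``carrier_lag_rad`` (``None`` gives
    independent carriers); a nonzero lag keeps the coupling visible to
    orthogonalizing estimators, which discard the zero-lag component.
    ``epochs`` optionally restricts the coupling to a list of
    ``(start_s, end_s)`` intervals; outside them the pair behaves like
    independent background.
    """

    pair: tuple[int, int]
    mode: str = "envelope"  # "envelope" | "phase"
    band_hz: float = 13.0
    strength: float = 0.6
    lag_rad: float = np.pi / 2
    kappa: float = 50.0
    carrier_lag_rad: float | None = np.pi / 2  # envelope mode: shared-carrier lag
    epochs: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        i, j = self.pair
        if i == j:
            raise ValueError("coupled parcel indices must be distinct")
        if self.mode not in ("envelope", "phase"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")
        if not 0.4 <= self.band_hz <= 45.0:
            raise ValueError("band_hz must lie in [0.4, 45] Hz")
        if self.mode == "envelope" and not 0.0 <= self.strength <= 1.0:
            raise ValueError("envelope strength must lie in [0, 1]")
        if self.mode == "phase" and self.kappa <= 0:
            raise ValueError("phase concentration kappa must be positive")


@dataclass(frozen=True)
class SpindleSpec:
    """Parameters of injected sleep-spindle bursts."""

    rate_per_min: float = 5.0
    freq_hz: float = 13.0
    duration_s: float = 1.0
    amplitude_rel: float = 3.0
    channels: np.ndarray | None = None  # spatial weight profile, len n_parcels

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ValueError("rate_per_min must be >= 0")
        if not 11.0 <= self.freq_hz <= 15.0:
            raise ValueError("spindle carrier must lie in [11, 15] Hz")
        if not 0.5 <= self.duration_s <= 3.0:
            raise ValueError("spindle duration must lie in [0.5, 3] s")
        if self.amplitude_rel <= 0:
            raise ValueError("amplitude_rel must be positive")


@dataclass(frozen=True)
class SpindleEvent:
    """One injected burst: exact half-open sample range plus profile tag."""

    start: int
    end: int
    profile: int = 0

    def as_seconds(self, fs: float) -> tuple[float, float]:
        return self.start / fs, self.end / fs


@dataclass
class CohortSpec:
    """A synthetic cohort with group-dependent coupling strength.

    ``n_per_group`` maps labels of ``group_axis`` (one of ``syndrome``,
    ``neuro_1y``, ``neuro_2y``) to subject counts.  Each subject's coupled
    pairs get envelope strength ``base_coupling + coupling_offsets[label]``
    (clipped to [0, 0.95]).  The remaining two label axes are filled from
    cohort-like marginals so every subject carries all three labels; the
    Typical(1y) -> Severe(2y) trajectory is never generated, matching its
    exclusion from trajectory analyses.
    """

    n_per_group: dict[str, int]
    group_axis: str = "neuro_2y"
    coupled_pairs: tuple[tuple[int, int], ...] = ((0, 1), (2, 3))
    mode: str = "envelope"
    band_hz: float = 13.0
    base_coupling: float = 0.4
    coupling_offsets: dict[str, float] = field(default_factory=dict)
    n_parcels: int = 12
    fs: float = 250.0
    duration_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_axis not in ("syndrome", "neuro_1y", "neuro_2y"):
            raise ValueError(f"unknown group axis {self.group_axis!r}")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} has no subjects")


# ---------------------------------------------------------------------------
# primitive signal builders


def background_noise(
    n_parcels: int,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    slope: float = 1.1,
    bump_hz: tuple[float, float] = (10.0, 14.0),
    bump_gain: float = 2.0,
) -> np.ndarray:
    """1/f^slope noise with a sigma-band resting bump, unit RMS per row.

    Spectral shaping is done in the frequency domain: white Gaussian noise
    is multiplied by ``f^(-slope/2)`` (power ~ 1/f^slope) plus a Gaussian
    amplitude bump centred in ``bump_hz``, mimicking infant N2 background.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-slope / 2.0)
    f0 = 0.5 * (bump_hz[0] + bump_hz[1])
    sd = (bump_hz[1] - bump_hz[0]) / 4.0
    amp += bump_gain * amp[np.searchsorted(freqs, f0)] * np.exp(
        -0.5 * ((freqs - f0) / sd) ** 2
    )
    spec = (
        rng.standard_normal((n_parcels, freqs.size))
        + 1j * rng.standard_normal((n_parcels, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def narrowband_carrier(
    n_samples: int,
    fs: float,
    fc: float,
    rng: np.random.Generator,
    bw: float | None = None,
) -> np.ndarray:
    """Constant-modulus complex narrow-band carrier centred at ``fc``.

    Complex Gaussian noise is spectrally confined to ``fc +- bw/2`` and then
    normalized to unit modulus, leaving a smooth random-walk phase.  The real
    part is a unit-envelope band-limited oscillation.
    """
    if bw is None:
        bw = max(0.3 * fc, 0.5)
    freqs = np.fft.fftfreq(n_samples, 1.0 / fs)
    mask = np.exp(-0.5 * ((freqs - fc) / (bw / 2.355)) ** 2)  # analytic: +f only
    spec = (
        rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples)
    ) * mask
    z = np.fft.ifft(spec)
    mod = np.abs(z)
    mod[mod == 0] = 1.0
    return z / mod


def _slow_gaussian(
    n_samples: int, fs: float, rng: np.random.Generator, band: tuple[float, float] = (0.1, 0.5)
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to a slow band."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.exp(-0.5 * ((freqs - np.mean(band)) / (0.5 * (band[1] - band[0]))) ** 2)
    amp[freqs == 0] = 0.0
    spec = (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    ) * amp
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _lognormal_alpha(rho: float, sigma: float) -> float:
    """Shared-modulator mixing weight realizing envelope correlation rho.

    If x, y are unit normals with correlation a, then
    corr(e^(s*x), e^(s*y)) = (e^(a s^2) - 1) / (e^(s^2) - 1); inverting for a
    and taking alpha = sqrt(a) (the shared-factor loading) gives the exact
    target Pearson correlation of the log-normal envelopes.
    """
    if rho <= 0.0:
        return 0.0
    a = math.log1p(rho * math.expm1(sigma**2)) / sigma**2
    return math.sqrt(min(a, 1.0))


def _epoch_indicator(
    epochs: tuple[tuple[float, float], ...] | None,
    n_samples: int,
    fs: float,
    ramp_s: float = 0.1,
) -> np.ndarray | None:
    """Smooth 0/1 gate for epoch-restricted coupling (raised-cosine ramps)."""
    if epochs is None:
        return None
    gate = np.zeros(n_samples)
    for t0, t1 in epochs:
        a, b = int(round(t0 * fs)), int(round(t1 * fs))
        a, b = max(a, 0), min(b, n_samples)
        if b <= a:
            continue
        gate[a:b] = 1.0
    nr = max(int(ramp_s * fs), 1)
    win = np.hanning(2 * nr + 1)
    win /= win.sum()
    return np.convolve(gate, win, mode="same")


# ---------------------------------------------------------------------------
# operations


def _check_specs(specs: Sequence[CouplingSpec], n_parcels: int) -> None:
    def span(s: CouplingSpec):
        return s.epochs  # None means the whole record

    seen: dict[int, list[CouplingSpec]] = {}
    for s in specs:
        for idx in s.pair:
            if not 0 <= idx < n_parcels:
                raise ValueError(f"parcel index {idx} out of range (n_parcels={n_parcels})")
            seen.setdefault(idx, []).append(s)
    for idx, members in seen.items():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = span(members[i]), span(members[j])
                overlap = (
                    a is None
                    or b is None
                    or any(t0 < u1 and u0 < t1 for t0, t1 in a for u0, u1 in b)
                )
                if overlap:
                    raise ValueError(
                        f"conflicting coupling specs share parcel {idx} over "
                        "overlapping epochs; split epochs or drop one spec"
                    )


def simulate_parcel_sources(
    specs: Sequence[CouplingSpec],
    n_parcels: int,
    fs: float,
    duration_s: float,
    seed: int,
    background_mix: float = 0.2,
    slope: float = 1.1,
) -> np.ndarray:
    """Generate ``n_parcels x (fs * duration_s)`` ground-truth source signals.

    Uncoupled parcels are independent 1/f background; coupled pairs realize
    the requested envelope correlation or phase-lag coupling exactly (see
    module docstring).  Coupled parcels keep a small independent background
    admixture (amplitude fraction ``background_mix``) so they are not
    pathologically noise-free.

    Deterministic given ``(specs, seed)``.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60 s")
    specs = list(specs)
    _check_specs(specs, n_parcels)
    n = int(round(fs * duration_s))
    rng = np.random.default_rng(seed)
    out = background_noise(n_parcels, n, fs, rng, slope=slope)

    for s in specs:
        i, j = s.pair
        gate = _epoch_indicator(s.epochs, n, fs)
        if s.mode == "envelope":
            sigma = 0.5
            alpha = _lognormal_alpha(s.strength, sigma)
            s0 = _slow_gaussian(n, fs, rng)
            env = []
            for _ in range(2):
                si = _slow_gaussian(n, fs, rng)
                x = alpha * s0 + math.sqrt(1.0 - alpha**2) * si
                env.append(np.exp(sigma * x))
            # narrow carrier: keeps the coupled oscillation well inside the
            # analysis band so filtering distorts the envelopes minimally
            bw = max(0.15 * s.band_hz, 0.4)
            zi = narrowband_carrier(n, fs, s.band_hz, rng, bw=bw)
            if s.carrier_lag_rad is None:
                zj = narrowband_carrier(n, fs, s.band_hz, rng, bw=bw)
            else:
                jitter = _slow_gaussian(n, fs, rng, band=(0.2, 1.0)) / math.sqrt(s.kappa)
                zj = zi * np.exp(-1j * (s.carrier_lag_rad + jitter))
            sig_i = env[0] * zi.real
            sig_j = env[1] * zj.real
        else:  # phase
            z = narrowband_carrier(n, fs, s.band_hz, rng)
            jitter = _slow_gaussian(n, fs, rng, band=(0.2, 1.0)) / math.sqrt(s.kappa)
            sig_i = z.real
            sig_j = (z * np.exp(-1j * (s.lag_rad + jitter))).real
        for idx, sig in ((i, sig_i), (j, sig_j)):
            sig = sig / np.sqrt(np.mean(sig**2))
            coupled = (
                math.sqrt(1.0 - background_mix**2) * sig + background_mix * out[idx]
            )
            if gate is None:
                out[idx] = coupled
            else:
                out[idx] = gate * coupled + (1.0 - gate) * out[idx]
    return out


def inject_spindles(
    sources: np.ndarray,
    spec: SpindleSpec | Sequence[SpindleSpec],
    fs: float,
    seed: int,
    guard_s: float = 0.2,
) -> tuple[np.ndarray, list[SpindleEvent]]:
    """Add raised-cosine spindle bursts; return exact truth intervals.

    Events are placed uniformly at random without overlap (a ``guard_s``
    buffer separates events, including across specs).  Raises if the
    requested rate cannot be placed without overlap.
    """
    specs = [spec] if isinstance(spec, SpindleSpec) else list(spec)
    n_parcels, n = sources.shape
    rng = np.random.default_rng(seed)
    out = sources.copy()
    events: list[SpindleEvent] = []
    occupied: list[tuple[int, int]] = []
    rms = np.sqrt(np.mean(sources**2, axis=1))

    for pid, sp in enumerate(specs):
        dur = int(round(sp.duration_s * fs))
        if dur > n:
            raise ValueError("spindle duration exceeds record length")
        guard = int(round(guard_s * fs))
        n_events = rng.poisson(sp.rate_per_min * (n / fs) / 60.0)
        profile = (
            np.ones(n_parcels) if sp.channels is None else np.asarray(sp.channels, float)
        )
        if profile.shape != (n_parcels,):
            raise ValueError("channel profile length must equal n_parcels")
        placed = 0
        tries = 0
        max_tries = 2000 * max(n_events, 1)
        while placed < n_events:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"spindle rate {sp.rate_per_min}/min too high to place "
                    "without overlapping events"
                )
            a = int(rng.integers(0, n - dur + 1))
            b = a + dur
            if any(a < e + guard and s - guard < b for s, e in occupied):
                continue
            occupied.append((a, b))
            t = np.arange(dur) / fs
            envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(dur) / (dur - 1)))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            burst = envelope * np.sin(2.0 * np.pi * sp.freq_hz * t + phase)
            out[:, a:b] += (sp.amplitude_rel * rms * profile)[:, None] * burst[None, :]
            events.append(SpindleEvent(start=a, end=b, profile=pid))
            placed += 1
    events.sort(key=lambda e: e.start)
    return out, events


def project_to_sensors(
    sources: np.ndarray,
    bundle,
    snr_db: float,
    seed: int,
    fs: float = 250.0,
) -> Recording:
    """Forward-project parcel sources to sensors and add white sensor noise.

    Every dipole carries its parcel's signal; sensor data are
    ``gain @ dipole_signals`` plus spatially white Gaussian noise scaled so
    the channel-average signal-to-noise power ratio equals ``snr_db``
    (``snr_db = inf`` means noise-free, ``-inf`` means signal-free noise of
    unit variance).
    """
    bundle_parcels = int(bundle.n_parcels)
    if sources.shape[0] != bundle_parcels:
        raise ValueError(
            f"source matrix has {sources.shape[0]} parcels, bundle expects {bundle_parcels}"
        )
    rng = np.random.default_rng(seed)
    dipoles = sources[bundle.parcel_map, :]
    if np.isneginf(snr_db):
        sensor = np.zeros((bundle.gain.shape[0], sources.shape[1]))
        noise = rng.standard_normal(sensor.shape)
        data = sensor + noise
    else:
        sensor = bundle.gain @ dipoles
        if np.isposinf(snr_db):
            data = sensor
        else:
            p_sig = np.mean(sensor**2)
            p_noise = p_sig / 10.0 ** (snr_db / 10.0)
            data = sensor + math.sqrt(p_noise) * rng.standard_normal(sensor.shape)
    return Recording(
        data=data,
        fs=fs,
        ch_names=list(bundle.sensor_names),
        positions=bundle.sensor_positions,
        reference="raw",
    )


# ---------------------------------------------------------------------------
# cohorts


def _fill_labels(axis: str, label: str, rng: np.random.Generator) -> dict[str, str]:
    """Fill the two label axes not used for grouping, consistently.

    Marginals loosely follow an infant-epilepsy cohort (West syndrome most
    common); the neuro trajectory never goes Typical(1y) -> Severe(2y).
    """
    lab: dict[str, str] = {axis: label}
    if "syndrome" not in lab:
        lab["syndrome"] = rng.choice(_SYNDROMES, p=(0.25, 0.55, 0.16, 0.04))
    if "neuro_2y" not in lab:
        if "neuro_1y" in lab:
            n1 = lab["neuro_1y"]
            choices = {"Typical": ("Typical", "Mild"), "Mild": _NEURO, "Severe": ("Mild", "Severe")}[n1]
            lab["neuro_2y"] = rng.choice(choices)
        else:
            lab["neuro_2y"] = rng.choice(_NEURO, p=(0.3, 0.2, 0.5))
    if "neuro_1y" not in lab:
        n2 = lab["neuro_2y"]
        choices = {"Typical": ("Typical",), "Mild": ("Typical", "Mild"), "Severe": ("Mild", "Severe")}[n2]
        lab["neuro_1y"] = rng.choice(choices)
    return lab


def generate_cohort(spec: CohortSpec):
    """Generate a manifest and per-subject ground-truth source matrices.

    Returns ``(manifest, sources, strengths)`` where ``manifest`` is a
    pandas DataFrame (subject_id, syndrome, neuro_1y, neuro_2y),
    ``sources`` is a list of parcel-source matrices and ``strengths`` the
    per-subject realized coupling strength.  Fully reproducible from
    ``spec.seed``.
    """
    import pandas as pd

    root = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    rows, sources, strengths = [], [], []
    sid = 0
    subject_seeds = root.spawn(sum(spec.n_per_group.values()))
    for label, count in spec.n_per_group.items():
        offset = spec.coupling_offsets.get(label, 0.0)
        strength = float(np.clip(spec.base_coupling + offset, 0.0, 0.95))
        for _ in range(count):
            lab = _fill_labels(spec.group_axis, label, label_rng)
            rows.append({"subject_id": f"S{sid:03d}", **lab})
            cspecs = [
                CouplingSpec(pair=p, mode=spec.mode, band_hz=spec.band_hz, strength=strength)
                for p in spec.coupled_pairs
            ]
            seed_i = int(subject_seeds[sid].generate_state(1)[0] % (2**31))
            sources.append(
                simulate_parcel_sources(
                    cspecs, spec.n_parcels, spec.fs, spec.duration_s, seed=seed_i
                )
            )
            strengths.append(strength)
            sid += 1
    manifest = pd.DataFrame(rows)[["subject_id", "syndrome", "neuro_1y", "neuro_2y"]]
    return manifest, sources, strengths


def simulate_cohort_matrices(
    n_per_group: dict[str, int],
    n_parcels: int = 58,
    effect_edges: int | Sequence[tuple[int, int]] = 100,
    effect: float = 0.3,
    effect_group: str | None = None,
    baseline: float = 0.1,
    noise_sd: float = 0.15,
    seed: int = 0,
):
    """Adjacency-matrix-level cohort: baseline + noise, effect on some edges.

    A desk-scale stand-in for a full signal-level cohort: each subject gets a
    symmetric matrix ``baseline + N(0, noise_sd)`` per edge, and subjects of
    ``effect_group`` (default: the last group) get ``effect`` added on
    ``effect_edges`` (a count, drawn at random, or an explicit edge list).

    Returns ``(groups, edges)``: a dict label -> (n, P, P) array with masked
    diagonal (np.nan), and the list of implanted edges.
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_parcels, k=1)
    n_edges = iu[0].size
    if isinstance(effect_edges, int):
        pick = rng.choice(n_edges, size=effect_edges, replace=False)
        edges = [(int(iu[0][k]), int(iu[1][k])) for k in pick]
    else:
        edges = [tuple(e) for e in effect_edges]
    if effect_group is None:
        effect_group = list(n_per_group)[-1]
    groups: dict[str, np.ndarray] = {}
    for label, count in n_per_group.items():
        mats = np.full((count, n_parcels, n_parcels), np.nan)
        vals = baseline + noise_sd * rng.standard_normal((count, n_edges))
        if label == effect_group:
            for i, j in edges:
                k = np.flatnonzero((iu[0] == i) & (iu[1] == j))[0]
                vals[:, k] += effect
        for s in range(count):
            m = np.full((n_parcels, n_parcels), np.nan)
            m[iu] = vals[s]
            m.T[iu] = vals[s]
            mats[s] = m
        groups[label] = mats
    return groups, edges
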