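"""Broadband conditioning and the geometric narrow-band filter ladder.

The analysis decomposes N2-sleep EEG into 25 narrow bands whose center
frequencies form a geometric ladder, ``fc[k] = f0 * ratio**k`` with
``f0 = 0.5`` Hz and ``ratio = 1.2`` (top band 39.7 Hz).  Each band is a
linear-phase Kaiser-window FIR band-pass with passband ``[0.85, 1.15]*fc``,
stopband ``[0.5, 1.5]*fc`` and at least 40 dB stopband attenuation.  Filters
are applied zero-phase (symmetric FIR, group delay compensated) per
continuous segment, and one filter length is dropped from each segment end
to remove edge transients — phase-based connectivity downstream must never
see filter transients or phase distortion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.special import eval_legendre

from .containers import Recording

__all__ = [
    "Band",
    "design_band_ladder",
    "design_kaiser_bandpass",
    "condition_broadband",
    "resample_recording",
    "rereference_average",
    "interpolate_bad_channels",
    "apply_filter_bank",
]

logger = logging.getLogger(__name__)

# design margin: aim a few dB past the contract so the *measured* response
# meets >= 40 dB exactly at the stopband edges
_RIPPLE_MARGIN_DB = 5.0
_WIDTH_SHRINK = 0.9


@dataclass(frozen=True)
class Band:
    """One narrow band of the ladder, defined entirely by its center fc."""

    fc: float
    attenuation_db: float = 40.0

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise ValueError("fc must be positive")
        if self.attenuation_db <= 0:
            raise ValueError("attenuation must be positive")

    @property
    def passband(self) -> tuple[float, float]:
        return (0.85 * self.fc, 1.15 * self.fc)

    @property
    def stopband(self) -> tuple[float, float]:
        return (0.5 * self.fc, 1.5 * self.fc)


def design_band_ladder(f0: float, ratio: float, n: int, fs: float | None = None) -> list[Band]:
    """Geometric ladder of ``n`` bands: ``fc[k] = f0 * ratio**k``.

    If ``fs`` is given, raises when a band's upper stopband edge reaches the
    Nyquist frequency, naming the offending band.
    """
    if f0 <= 0 or ratio <= 1 or n < 1:
        raise ValueError("need f0 > 0, ratio > 1, n >= 1")
    bands = [Band(fc=f0 * ratio ** k) for k in range(n)]
    if fs is not None:
        for k, b in enumerate(bands):
            if b.stopband[1] >= fs / 2:
                raise ValueError(
                    f"band {k + 1} (fc={b.fc:.2f} Hz) has stopband edge "
                    f"{b.stopband[1]:.2f} Hz >= Nyquist ({fs / 2:.1f} Hz)"
                )
    return bands


def design_kaiser_bandpass(band: Band, fs: float, max_taps: int = 100_000) -> np.ndarray:
    """Linear-phase Kaiser FIR band-pass meeting the band's contract.

    Cutoffs sit at the transition-band midpoints; the Kaiser order/beta rule
    is driven by the narrower transition band with a small design margin so
    the measured response is at or below -40 dB at both stopband edges and
    within 1 dB of unity at fc.  Returns the (odd-length, symmetric) taps.
    """
    if band.stopband[1] >= fs / 2:
        raise ValueError(
            f"band fc={band.fc:.3g} Hz: stopband edge {band.stopband[1]:.3g} Hz "
            f"not below Nyquist ({fs / 2:.3g} Hz)"
        )
    (sb_lo, sb_hi), (pb_lo, pb_hi) = band.stopband, band.passband
    width_hz = _WIDTH_SHRINK * min(pb_lo - sb_lo, sb_hi - pb_hi)
    numtaps, beta = sps.kaiserord(
        band.attenuation_db + _RIPPLE_MARGIN_DB, width_hz / (fs / 2.0)
    )
    numtaps |= 1  # odd length -> type-I FIR, exact symmetry
    if numtaps > max_taps:
        raise ValueError(
            f"band fc={band.fc:.3g} Hz needs {numtaps} taps at fs={fs} Hz "
            f"(cap {max_taps}); transition width infeasible"
        )
    cutoffs = [0.5 * (sb_lo + pb_lo), 0.5 * (pb_hi + sb_hi)]
    return sps.firwin(numtaps, cutoffs, window=("kaiser", beta), pass_zero=False, fs=fs)


def condition_broadband(
    rec: Recording,
    lo: float = 0.15,
    hi: float = 48.0,
    transition_lo: float = 0.1,
    transition_hi: float = 4.0,
    attenuation_db: float = 40.0,
) -> Recording:
    """Broadband 0.15-48 Hz conditioning with the same Kaiser design.

    Transients of half the filter length are dropped from each segment end
    (the broadband filter is long because of the 0.15 Hz edge; the full
    ladder trimming rule would be needlessly destructive here).
    """
    fs = rec.fs
    width = min(transition_lo, transition_hi)
    numtaps, beta = sps.kaiserord(attenuation_db + _RIPPLE_MARGIN_DB, width / (fs / 2.0))
    numtaps |= 1
    cutoffs = [max(lo - transition_lo / 2.0, 0.01), hi + transition_hi / 2.0]
    taps = sps.firwin(numtaps, cutoffs, window=("kaiser", beta), pass_zero=False, fs=fs)
    return _filter_segments(rec, taps, trim=numtaps // 2)


def resample_recording(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling (anti-aliased) to ``target_fs``, per segment."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > rec.fs:
        raise ValueError("upsampling is not part of this pipeline")
    if target_fs == rec.fs:
        return rec.copy()
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    pieces, segments, pos = [], [], 0
    for (_, _), seg in rec.iter_segments():
        y = sps.resample_poly(seg, up, down, axis=1)
        pieces.append(y)
        segments.append((pos, pos + y.shape[1]))
        pos += y.shape[1]
    return rec.copy(data=np.concatenate(pieces, axis=1), fs=float(target_fs), segments=segments)


def rereference_average(rec: Recording) -> Recording:
    """Common-average reference: subtract the per-sample channel mean."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy(data=data, reference="average")


# ---------------------------------------------------------------------------
# spherical spline interpolation (Perrin et al. style)


def _gfun(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical spline kernel g(cos gamma) as a truncated Legendre series."""
    n = np.arange(1, n_terms + 1, dtype=float)
    coef = (2.0 * n + 1.0) / (n * (n + 1.0)) ** stiffness
    cosang = np.clip(np.asarray(cosang, float), -1.0, 1.0)
    out = np.zeros_like(cosang)
    for ni, ci in zip(n.astype(int), coef):
        out += ci * eval_legendre(ni, cosang)
    return out / (4.0 * np.pi)


def spline_interpolation_matrix(
    pos_good: np.ndarray, pos_bad: np.ndarray, reg: float = 1e-5
) -> np.ndarray:
    """Operator mapping good-channel data to spherical-spline estimates.

    Solves the constrained spline system (kernel matrix plus constant term,
    weights summing to zero) on the good electrodes and evaluates it at the
    bad electrode positions.
    """
    k = pos_good.shape[0]
    G = _gfun(pos_good @ pos_good.T) + reg * np.eye(k)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    Ainv = np.linalg.pinv(A)
    Gb = _gfun(pos_bad @ pos_good.T)
    # data enters as [v; 0]; estimate = [Gb, 1] @ Ainv @ [v; 0]
    return np.hstack([Gb, np.ones((pos_bad.shape[0], 1))]) @ Ainv[:, :k]


def interpolate_bad_channels(rec: Recording, bad: list[str] | None = None) -> Recording:
    """Replace bad channels by spherical-spline estimates from good ones."""
    bad = rec.bads if bad is None else bad
    if not bad:
        return rec.copy()
    if rec.positions is None:
        raise ValueError("montage positions required for spline interpolation")
    unknown = set(bad) - set(rec.ch_names)
    if unknown:
        raise ValueError(f"bad channels not in montage: {sorted(unknown)}")
    if len(bad) >= rec.n_channels / 4:
        raise ValueError("more than a quarter of channels marked bad")
    bad_idx = [rec.ch_names.index(b) for b in bad]
    good_idx = [i for i in range(rec.n_channels) if i not in bad_idx]
    M = spline_interpolation_matrix(rec.positions[good_idx], rec.positions[bad_idx])
    data = rec.data.copy()
    data[bad_idx] = M @ rec.data[good_idx]
    return rec.copy(data=data, bads=[])


# ---------------------------------------------------------------------------
# filter application


def _filter_segments(rec: Recording, taps: np.ndarray, trim: int) -> Recording:
    """Zero-phase FIR per segment; drop ``trim`` samples from each end."""
    ntaps = taps.size
    pieces, segments, pos = [], [], 0
    for (a, b), seg in rec.iter_segments():
        if seg.shape[1] < 3 * ntaps:
            logger.warning(
                "segment [%d, %d) shorter than 3x filter length (%d); skipped", a, b, ntaps
            )
            continue
        y = sps.fftconvolve(seg, taps[None, :], mode="same", axes=1)
        y = y[:, trim: y.shape[1] - trim] if trim else y
        pieces.append(y)
        segments.append((pos, pos + y.shape[1]))
        pos += y.shape[1]
    if not pieces:
        raise ValueError("no segment long enough for this filter")
    return rec.copy(data=np.concatenate(pieces, axis=1), segments=segments)


def apply_filter_bank(
    rec: Recording, bands: list[Band], trim_full_length: bool = True
) -> dict[float, Recording]:
    """Apply each band's zero-phase FIR per segment; returns ``{fc: Recording}``.

    Segments shorter than three filter lengths at a band are skipped for
    that band (logged).  One filter length is trimmed from each segment end
    by default; passing ``trim_full_length=False`` trims half a length.
    """
    out: dict[float, Recording] = {}
    for band in bands:
        taps = design_kaiser_bandpass(band, rec.fs)
        trim = taps.size if trim_full_length else taps.size // 2
        filtered = _filter_segments(rec, taps, trim=trim)
        filtered.meta = dict(filtered.meta, band_fc=band.fc)
        out[band.fc] = filtered
    return out
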