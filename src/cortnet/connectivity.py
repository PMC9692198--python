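"""Amplitude (oCC) and phase (dwPLI) connectivity between parcel signals.

Two coupling modes are estimated from Hilbert-transformed narrow-band
parcel signals:

* **oCC** (orthogonalized correlation coefficient, the AAC estimate).  In
  non-overlapping windows the analytic signal of one parcel is
  orthogonalized against the other — ``y_perp = Im(y * conj(x) / |x|)`` —
  which removes the instantaneous zero-lag (volume-conducted) component by
  construction.  The Pearson correlation between the concatenated
  window-wise envelopes of ``y_perp`` and ``|x|`` is computed, the roles
  are swapped, and the two coefficients are averaged.  Values lie in
  [-1, 1]; a signal orthogonalized against itself vanishes, so pure
  zero-lag mixing yields zero.

* **dwPLI** (debiased squared weighted phase lag index, the PPC estimate).
  Each window contributes one imaginary cross-spectral sample
  ``I_j = Im(mean(x * conj(y)))``; the debiased estimator is
  ``[(sum I)^2 - sum I^2] / [(sum |I|)^2 - sum I^2]``, which removes the
  positive small-sample bias of the squared PLI and ignores zero-lag
  coupling (all-real cross-spectra give zero by convention).  Raw values
  may be slightly negative; the adjacency matrix stores a copy clipped to
  [0, 1] while the raw value is kept for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .containers import ParcelSignals

__all__ = [
    "AdjacencyMatrix",
    "analytic_signal",
    "occ",
    "dwpli",
    "pli_squared",
    "connectivity_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyMatrix:
    """Symmetric parcel-pair connectivity matrix for one subject x band x mode.

    ``values`` holds NaN on the diagonal and on masked (invalid or pruned)
    cells; ``valid`` is the boolean mask of computed, unpruned off-diagonal
    cells.  For PPC, ``raw`` keeps the unclipped dwPLI values.
    """

    values: np.ndarray
    mode: str  # "AAC" | "PPC"
    band_fc: float | None = None
    subject_id: str | None = None
    n_windows: int = 0
    valid: np.ndarray | None = None
    raw: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency matrix must be square")
        off = ~np.eye(v.shape[0], dtype=bool)
        finite = off & np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite], atol=1e-12):
            raise ValueError("adjacency matrix must be symmetric")
        if self.valid is None:
            self.valid = finite
        self.values = v

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def global_mean(self) -> float:
        """Mean over valid (unmasked, off-diagonal) cells."""
        return float(np.nanmean(self.values[self.valid]))

    def pair_values(self) -> np.ndarray:
        """Upper-triangle values (NaN where masked)."""
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.values[iu]


def analytic_signal(
    x: np.ndarray,
    segments: list[tuple[int, int]] | None = None,
    fs: float | None = None,
    fc: float | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Hilbert analytic signal per continuous segment.

    ``x`` is real, 1-D or (channels, samples).  Segments shorter than two
    cycles of ``fc`` (when ``fs`` and ``fc`` are given) are skipped with a
    log entry and excluded from the returned segment list; their samples
    are zero in the output.  Returns ``(z, segments_used)``.
    """
    x = np.asarray(x, float)
    one_d = x.ndim == 1
    data = x[None, :] if one_d else x
    n = data.shape[1]
    segments = segments or [(0, n)]
    min_len = 0 if (fs is None or fc is None) else int(np.ceil(2.0 * fs / fc))
    z = np.zeros(data.shape, dtype=complex)
    kept: list[tuple[int, int]] = []
    for a, b in segments:
        if b - a < max(min_len, 4):
            logger.warning("segment [%d, %d) shorter than 2 cycles of fc; skipped", a, b)
            continue
        z[:, a:b] = hilbert(data[:, a:b], axis=1)
        kept.append((a, b))
    return (z[0] if one_d else z), kept


def _window_slices(
    segments: list[tuple[int, int]], win: int
) -> list[tuple[int, int]]:
    """Non-overlapping full windows inside each segment."""
    out = []
    for a, b in segments:
        n_win = (b - a) // win
        out.extend((a + k * win, a + (k + 1) * win) for k in range(n_win))
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def occ(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    segments: list[tuple[int, int]] | None = None,
    min_windows: int = 30,
    log_envelopes: bool = False,
) -> float:
    """Orthogonalized envelope correlation between two analytic signals.

    ``x`` and ``y`` are complex analytic signals of equal length.  Raises
    ``ValueError`` when fewer than ``min_windows`` full windows are
    available; returns 0.0 when either envelope is degenerate (zero
    throughout).  ``log_envelopes`` switches the Pearson step to
    log-transformed envelopes.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    win = int(round(window_s * fs))
    slices = _window_slices(segments or [(0, x.size)], win)
    if len(slices) < min_windows:
        raise ValueError(
            f"only {len(slices)} usable windows (< {min_windows}); record too short"
        )
    idx = np.concatenate([np.arange(a, b) for a, b in slices])
    xs, ys = x[idx], y[idx]
    ax, ay = np.abs(xs), np.abs(ys)
    if not ax.any() or not ay.any():
        return 0.0

    def one_way(z_ref, env_ref, z_other):
        safe = np.where(env_ref == 0, 1.0, env_ref)
        resid_env = np.abs(np.imag(z_other * np.conj(z_ref) / safe))
        # identical signals leave ~1e-17 float residue; snap to the exact
        # self-orthogonalization zero so y = x returns 0, not noise
        resid_env[resid_env < 1e-12 * np.abs(z_other)] = 0.0
        if log_envelopes:
            eps = np.finfo(float).tiny
            return _pearson(np.log(resid_env + eps), np.log(env_ref + eps))
        return _pearson(resid_env, env_ref)

    return 0.5 * (one_way(xs, ax, ys) + one_way(ys, ay, xs))


def _window_imag_cross(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float,
    segments: list[tuple[int, int]] | None,
    min_windows: int,
) -> np.ndarray:
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    win = int(round(window_s * fs))
    slices = _window_slices(segments or [(0, x.size)], win)
    if len(slices) < min_windows:
        raise ValueError(
            f"only {len(slices)} usable windows (< {min_windows}); record too short"
        )
    imag = np.array([np.imag(np.mean(x[a:b] * np.conj(y[a:b]))) for a, b in slices])
    # exact zero-lag leaves ~1e-18 float residue in Im(z conj(z)); snap it to
    # the zero-by-convention branch instead of letting its sign be noise
    power = np.array([np.mean(np.abs(x[a:b]) * np.abs(y[a:b])) for a, b in slices])
    imag[np.abs(imag) < 1e-12 * np.maximum(power, np.finfo(float).tiny)] = 0.0
    return imag


def dwpli(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    segments: list[tuple[int, int]] | None = None,
    min_windows: int = 30,
) -> float:
    """Debiased squared weighted phase lag index from windowed cross-spectra.

    Returns the raw (possibly slightly negative) debiased estimate; zero by
    convention when every imaginary cross-spectrum vanishes (pure zero-lag).
    """
    imag = _window_imag_cross(x, y, fs, window_s, segments, min_windows)
    sum_i = imag.sum()
    sum_i2 = (imag**2).sum()
    sum_abs = np.abs(imag).sum()
    denom = sum_abs**2 - sum_i2
    if denom == 0:
        return 0.0
    return float((sum_i**2 - sum_i2) / denom)


def pli_squared(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    segments: list[tuple[int, int]] | None = None,
    min_windows: int = 30,
) -> float:
    """Non-debiased squared phase lag index (positively biased null ~ 1/n)."""
    imag = _window_imag_cross(x, y, fs, window_s, segments, min_windows)
    return float(np.mean(np.sign(imag)) ** 2)


def default_window_s(mode: str, band_fc: float | None) -> float:
    """oCC uses 1-s windows; dwPLI windows are max(1 s, 4 cycles of fc)."""
    if mode == "AAC" or band_fc is None:
        return 1.0
    return max(1.0, 4.0 / band_fc)


def connectivity_matrix(
    parcels: ParcelSignals,
    mode: str,
    window_s: float | None = None,
    min_windows: int = 30,
    subject_id: str | None = None,
) -> AdjacencyMatrix:
    """All-pairs adjacency matrix (n(n-1)/2 unordered pairs) for one mode.

    Pairs with fewer than ``min_windows`` usable windows are masked (NaN),
    never silently zero.  For PPC the stored values are clipped to [0, 1]
    and the raw dwPLI kept in ``raw``.
    """
    if mode not in ("AAC", "PPC"):
        raise ValueError("mode must be 'AAC' or 'PPC'")
    n = parcels.n_parcels
    z, segs = analytic_signal(
        parcels.data, segments=parcels.segments, fs=parcels.fs, fc=parcels.band_fc
    )
    if window_s is None:
        window_s = default_window_s(mode, parcels.band_fc)
    win = int(round(window_s * parcels.fs))
    n_windows = len(_window_slices(segs, win))
    values = np.full((n, n), np.nan)
    raw = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if mode == "AAC":
                    v = occ(z[i], z[j], parcels.fs, window_s, segs, min_windows)
                    r = v
                else:
                    r = dwpli(z[i], z[j], parcels.fs, window_s, segs, min_windows)
                    v = max(r, 0.0)
            except ValueError:
                continue  # masked cell
            values[i, j] = values[j, i] = v
            raw[i, j] = raw[j, i] = r
    return AdjacencyMatrix(
        values=values,
        mode=mode,
        band_fc=parcels.band_fc,
        subject_id=subject_id,
        n_windows=n_windows,
        raw=raw,
    )
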