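"""Forward model, minimum-norm/dSPM inverse, and parcel collapse.

The desk-scale forward model places radially oriented dipoles on an inner
sphere and sensors on the unit sphere and computes the surface potential
from the homogeneous-sphere analytic series

    V(gamma) = q / (4 pi sigma R^2) * sum_n (2n+1) f^(n-1) P_n(cos gamma),

with ``f`` the fractional source depth (derived from the monopole Legendre
expansion with an insulating boundary).  A user-supplied gain matrix and
parcel assignment can replace the toy geometry for real head models; the
three-compartment conductivities (intracranial, skull, scalp) are carried
as metadata for such models.

The inverse is the classic minimum-norm kernel ``K = G' (G G' + lam C)^-1``
with identity noise covariance ``C`` and no depth prior, with per-source
dSPM normalization ``sqrt(diag(K C K'))``.  Dipole estimates are collapsed
to parcels by the plain arithmetic mean of member dipole time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

from .containers import ParcelSignals, Recording

__all__ = [
    "LeadFieldBundle",
    "InverseOperator",
    "make_toy_bundle",
    "make_identity_bundle",
    "compute_inverse_operator",
    "reconstruct_sources",
    "collapse_to_parcels",
    "parcel_operator",
]

DEFAULT_CONDUCTIVITIES = (1.79, 0.1, 0.43)  # intracranial, skull, scalp (S/m)

_REGIONS = ("F", "C", "T", "O")


@dataclass
class LeadFieldBundle:
    """Gain matrix plus source geometry and parcellation."""

    gain: np.ndarray  # (n_sensors, n_sources)
    source_positions: np.ndarray  # (n_sources, 3)
    source_orientations: np.ndarray  # (n_sources, 3), fixed (radial)
    parcel_map: np.ndarray  # (n_sources,) int, source -> parcel
    centroids: np.ndarray  # (n_parcels, 3)
    region_labels: list[str]  # e.g. "F-left"
    sensor_positions: np.ndarray  # (n_sensors, 3)
    sensor_names: list[str]
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, float)
        self.parcel_map = np.asarray(self.parcel_map, int)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain matrix contains non-finite values")
        if self.parcel_map.shape != (self.gain.shape[1],):
            raise ValueError("parcel_map length must equal the number of sources")
        counts = np.bincount(self.parcel_map, minlength=self.n_parcels)
        if np.any(counts == 0):
            raise ValueError("every parcel must contain at least one source")
        if len(self.region_labels) != self.n_parcels:
            raise ValueError("region labels must cover all parcels")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def n_parcels(self) -> int:
        return int(self.parcel_map.max()) + 1

    def collapse_matrix(self) -> np.ndarray:
        """(n_parcels, n_sources) averaging matrix implementing the collapse."""
        P = np.zeros((self.n_parcels, self.n_sources))
        counts = np.bincount(self.parcel_map, minlength=self.n_parcels)
        P[self.parcel_map, np.arange(self.n_sources)] = 1.0 / counts[self.parcel_map]
        return P


@dataclass
class InverseOperator:
    """Minimum-norm kernel with dSPM normalization factors."""

    kernel: np.ndarray  # (n_sources, n_sensors)
    dspm_norm: np.ndarray  # (n_sources,)
    lam: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("inverse kernel contains non-finite values")
        if np.any(self.dspm_norm <= 0):
            raise ValueError("dSPM normalization factors must be positive")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sphere_gain_radial(
    sensor_dirs: np.ndarray, source_pos: np.ndarray, n_terms: int = 60, sigma: float = 1.0
) -> np.ndarray:
    """Surface potential of radial dipoles in a homogeneous unit sphere."""
    radii = np.linalg.norm(source_pos, axis=1)
    if np.any(radii >= 1.0):
        raise ValueError("sources must lie strictly inside the unit sphere")
    dirs = source_pos / radii[:, None]
    cosang = np.clip(sensor_dirs @ dirs.T, -1.0, 1.0)
    gain = np.zeros_like(cosang)
    for n in range(1, n_terms + 1):
        gain += (2 * n + 1) * radii[None, :] ** (n - 1) * eval_legendre(n, cosang)
    return gain / (4.0 * np.pi * sigma)


def _region_label(v: np.ndarray) -> str:
    hemi = "left" if v[0] < 0 else "right"
    if v[1] > 0.35:
        reg = "F"
    elif v[1] < -0.35:
        reg = "O"
    else:
        reg = "C" if v[2] > 0 else "T"
    return f"{reg}-{hemi}"


def make_toy_bundle(
    n_sensors: int = 64,
    n_sources: int = 1024,
    n_parcels: int = 58,
    seed: int = 0,
    depth_range: tuple[float, float] = (0.70, 0.87),
) -> LeadFieldBundle:
    """Desk-scale spherical head model with an angular parcellation.

    Sensors sit on the unit sphere, radial dipoles on an inner shell with
    seeded depth jitter; parcels are contiguous angular patches from k-means
    on the source directions, labelled by spherical octant (F/C/T/O x
    left/right).
    """
    if n_parcels < 2 or n_sources < n_parcels or n_sensors < 8:
        raise ValueError("infeasible counts: need n_sources >= n_parcels >= 2, n_sensors >= 8")
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    sensor_pos = _fibonacci_sphere(n_sensors)
    dirs = _fibonacci_sphere(n_sources)
    radii = rng.uniform(*depth_range, size=n_sources)
    src_pos = dirs * radii[:, None]
    gain = sphere_gain_radial(sensor_pos, src_pos)
    km = KMeans(n_clusters=n_parcels, n_init=4, random_state=seed)
    parcel_map = km.fit_predict(dirs)
    centroids = np.vstack(
        [src_pos[parcel_map == p].mean(axis=0) for p in range(n_parcels)]
    )
    labels = [_region_label(c / np.linalg.norm(c)) for c in centroids]
    return LeadFieldBundle(
        gain=gain,
        source_positions=src_pos,
        source_orientations=dirs,
        parcel_map=parcel_map,
        centroids=centroids,
        region_labels=labels,
        sensor_positions=sensor_pos,
        sensor_names=[f"E{i + 1:02d}" for i in range(n_sensors)],
        meta={"geometry": "toy-1shell-sphere", "seed": seed},
    )


def make_identity_bundle(n: int) -> LeadFieldBundle:
    """One sensor per parcel, unit gain: the pipeline's null transformation."""
    pos = _fibonacci_sphere(n)
    labels = [_region_label(p) for p in pos]
    return LeadFieldBundle(
        gain=np.eye(n),
        source_positions=0.8 * pos,
        source_orientations=pos,
        parcel_map=np.arange(n),
        centroids=0.8 * pos,
        region_labels=labels,
        sensor_positions=pos,
        sensor_names=[f"E{i + 1:02d}" for i in range(n)],
        meta={"geometry": "identity"},
    )


def compute_inverse_operator(
    bundle: LeadFieldBundle, lam: float | None = None, snr: float = 3.0
) -> InverseOperator:
    """Minimum-norm kernel with identity noise covariance and dSPM norms.

    ``lam`` defaults to the SNR rule ``trace(G G') / (n_sensors * snr**2)``.
    """
    G = bundle.gain
    gram = G @ G.T
    if lam is None:
        lam = float(np.trace(gram)) / (G.shape[0] * snr**2)
    if lam <= 0:
        raise ValueError("regularization lam must be positive")
    A = gram + lam * np.eye(G.shape[0])
    try:
        kernel = np.linalg.solve(A, G).T  # = G' (G G' + lam I)^-1
    except np.linalg.LinAlgError as err:  # pragma: no cover - lam > 0 keeps A SPD
        raise ValueError(f"singular sensor gram matrix (cond issue): {err}") from err
    dspm_norm = np.sqrt(np.sum(kernel**2, axis=1))
    dspm_norm[dspm_norm == 0] = np.finfo(float).tiny
    return InverseOperator(kernel=kernel, dspm_norm=dspm_norm, lam=lam)


def reconstruct_sources(
    rec: Recording, inv: InverseOperator, dspm: bool = True
) -> np.ndarray:
    """Apply the inverse kernel to sensor data (linear; segments untouched)."""
    if rec.n_channels != inv.kernel.shape[1]:
        raise ValueError(
            f"recording has {rec.n_channels} channels, kernel expects {inv.kernel.shape[1]}"
        )
    est = inv.kernel @ rec.data
    if dspm:
        est = est / inv.dspm_norm[:, None]
    return est


def collapse_to_parcels(
    sources: np.ndarray,
    bundle: LeadFieldBundle,
    fs: float = 250.0,
    segments: list[tuple[int, int]] | None = None,
    band_fc: float | None = None,
) -> ParcelSignals:
    """Mean of member dipole time courses per parcel."""
    if sources.shape[0] != bundle.n_sources:
        raise ValueError("source count does not match bundle")
    data = bundle.collapse_matrix() @ sources
    return ParcelSignals(
        data=data,
        fs=fs,
        band_fc=band_fc,
        segments=segments or [],
        parcel_labels=list(bundle.region_labels),
    )


def parcel_operator(
    inv: InverseOperator, bundle: LeadFieldBundle, dspm: bool = True
) -> np.ndarray:
    """(n_parcels, n_sensors) map: the whole sensor->parcel chain as one matrix."""
    K = inv.kernel / inv.dspm_norm[:, None] if dspm else inv.kernel
    return bundle.collapse_matrix() @ K
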