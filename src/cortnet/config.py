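"""Pipeline configuration with the published analysis defaults.

Defaults mirror the printed analysis parameters: 250 Hz target rate, a
25-band geometric ladder from 0.5 Hz with ratio 1.2, Kaiser filters at
40 dB attenuation with stopband/passband edges at 0.5/1.5 and 0.85/1.15 of
fc, fidelity pruning with 500 iterations against the surrogate 99th
percentile, and edge-wise statistics at alpha = 0.05.  Any override is
recorded in the run's provenance file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class LadderConfig:
    f0: float = 0.5
    ratio: float = 1.2
    n: int = 25


@dataclass
class FilterConfig:
    attenuation_db: float = 40.0
    stopband_rel: tuple[float, float] = (0.5, 1.5)
    passband_rel: tuple[float, float] = (0.85, 1.15)


@dataclass
class SpindleConfig:
    band: tuple[float, float] = (11.0, 15.0)
    k_upper: float = 3.0
    k_lower: float = 1.5
    min_dur_s: float = 0.5
    max_dur_s: float = 3.0
    theta: float = 0.5
    gap_s: float = 1.0
    pad_s: float = 0.25


@dataclass
class InverseConfig:
    lam: float | None = None  # None -> SNR rule
    snr: float = 3.0


@dataclass
class FidelityConfig:
    n_iter: int = 500
    percentile: float = 99.0
    band_hz: float = 10.0
    duration_s: float = 4.0


@dataclass
class BundleConfig:
    kind: str = "toy"  # "toy" | "identity" | "file"
    n_sensors: int = 64
    n_sources: int = 1024
    n_parcels: int = 58
    path: str | None = None


@dataclass
class PipelineConfig:
    fs_target: float = 250.0
    ladder: LadderConfig = field(default_factory=LadderConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    spindle: SpindleConfig = field(default_factory=SpindleConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)
    fidelity: FidelityConfig = field(default_factory=FidelityConfig)
    bundle: BundleConfig = field(default_factory=BundleConfig)
    alpha: float = 0.05
    modes: tuple[str, ...] = ("AAC", "PPC")
    band_subset: tuple[int, ...] | None = None  # indices into the ladder
    grouping: str = "neuro_2y"
    min_windows: int = 30
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict()))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sub = {
            "ladder": LadderConfig,
            "filter": FilterConfig,
            "spindle": SpindleConfig,
            "inverse": InverseConfig,
            "fidelity": FidelityConfig,
            "bundle": BundleConfig,
        }
        kwargs = {}
        for k, v in raw.items():
            if k in sub and isinstance(v, dict):
                kwargs[k] = sub[k](**{kk: _detuple(vv) for kk, vv in v.items()})
            else:
                kwargs[k] = _detuple(v)
        return cls(**kwargs)

    def content_hash(self) -> str:
        """Stable hash of the full configuration (cache key)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _detuple(v):
    return tuple(v) if isinstance(v, list) else v
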