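"""File formats: EDF ingestion/export, HDF5 tensors, JSON/TSV tables.

EDF is used only at the recording boundary (16-bit, physical scaling in
microvolts): a minimal EDF writer is implemented here (the format is a
fixed-layout ASCII header plus int16 data records) and reading goes through
``mne.io.read_raw_edf``.  Everything downstream is stored as HDF5 (arrays),
CSV/TSV (tables) or JSON (annotations, provenance), so cached intermediates
are bit-exact and human-auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Recording
from .sourcemodel import LeadFieldBundle
from .spindles import SpindleAnnotations

__all__ = [
    "write_edf",
    "read_edf",
    "write_recording_h5",
    "read_recording_h5",
    "write_bundle_h5",
    "read_bundle_h5",
    "write_matrix_tensor",
    "read_matrix_tensor",
    "write_intervals_json",
    "read_intervals_json",
    "write_annotations",
    "read_annotations",
    "write_mask_tsv",
    "load_manifest",
]

_SYNDROMES = {"self-limited", "West", "unclassified focal", "other"}
_NEURO = {"Typical", "Mild", "Severe"}


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with physical scaling in microvolts.

    Uses 1-s data records; the tail is truncated to whole records.  Segment
    structure is not representable in plain EDF and is dropped (store HDF5
    alongside when cuts must survive a round trip).
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-s EDF record")
    nch = rec.n_channels
    data = rec.data[:, : n_rec * spr]
    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None]) + dig_min, dig_min, dig_max
    ).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + nch)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(nch), 4),
        ]
    )
    fields = [
        (16, [ch for ch in rec.ch_names]),
        (80, ["" for _ in range(nch)]),
        (8, ["uV"] * nch),
        (8, [f"{v:.6g}"[:8] for v in phys_min]),
        (8, [f"{v:.6g}"[:8] for v in phys_max]),
        (8, [str(dig_min)] * nch),
        (8, [str(dig_max)] * nch),
        (80, ["" for _ in range(nch)]),
        (8, [str(spr)] * nch),
        (32, ["" for _ in range(nch)]),
    ]
    sig_header = b"".join(
        b"".join(_pad(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as f:
        f.write(header + sig_header)
        for r in range(n_rec):
            block = digital[:, r * spr: (r + 1) * spr]
            f.write(block.tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        reference="as-recorded",
    )


def write_recording_h5(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["reference"] = rec.reference
        f.create_dataset("ch_names", data=np.array(rec.ch_names, dtype="S"))
        if rec.positions is not None:
            f.create_dataset("positions", data=rec.positions)
        f.create_dataset("segments", data=np.array(rec.segments, int))
        f.create_dataset("bads", data=np.array(rec.bads, dtype="S"))
    return path


def read_recording_h5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            ch_names=[s.decode() for s in f["ch_names"][()]],
            positions=f["positions"][()] if "positions" in f else None,
            reference=str(f.attrs.get("reference", "unknown")),
            bads=[s.decode() for s in f["bads"][()]],
            segments=[tuple(s) for s in f["segments"][()]],
        )


def write_bundle_h5(bundle: LeadFieldBundle, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=bundle.gain)
        f.create_dataset("positions", data=bundle.source_positions)
        f.create_dataset("orientations", data=bundle.source_orientations)
        f.create_dataset("parcel_map", data=bundle.parcel_map)
        f.create_dataset("centroids", data=bundle.centroids)
        f.create_dataset("region_labels", data=np.array(bundle.region_labels, dtype="S"))
        f.create_dataset("sensor_positions", data=bundle.sensor_positions)
        f.create_dataset("sensor_names", data=np.array(bundle.sensor_names, dtype="S"))
        f.attrs["conductivities"] = bundle.conductivities
    return path


def read_bundle_h5(path: str | Path) -> LeadFieldBundle:
    with h5py.File(path, "r") as f:
        return LeadFieldBundle(
            gain=f["gain"][()],
            source_positions=f["positions"][()],
            source_orientations=f["orientations"][()],
            parcel_map=f["parcel_map"][()],
            centroids=f["centroids"][()],
            region_labels=[s.decode() for s in f["region_labels"][()]],
            sensor_positions=f["sensor_positions"][()],
            sensor_names=[s.decode() for s in f["sensor_names"][()]],
            conductivities=tuple(f.attrs["conductivities"]),
        )


def write_matrix_tensor(
    path: str | Path,
    tensor: np.ndarray,
    subjects: list[str],
    band_fcs: list[float],
    modes: list[str],
) -> Path:
    """Store a subjects x bands x modes x P x P connectivity tensor."""
    path = Path(path)
    if tensor.shape[:3] != (len(subjects), len(band_fcs), len(modes)):
        raise ValueError("tensor leading dims must match subjects/bands/modes")
    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=tensor)
        f.create_dataset("subjects", data=np.array(subjects, dtype="S"))
        f.create_dataset("band_fcs", data=np.array(band_fcs, float))
        f.create_dataset("modes", data=np.array(modes, dtype="S"))
    return path


def read_matrix_tensor(path: str | Path):
    with h5py.File(path, "r") as f:
        return (
            f["tensor"][()],
            [s.decode() for s in f["subjects"][()]],
            list(f["band_fcs"][()]),
            [s.decode() for s in f["modes"][()]],
        )


def write_intervals_json(intervals, path: str | Path, **meta) -> Path:
    """Half-open [start, end) intervals in seconds as JSON."""
    path = Path(path)
    payload = {"intervals": [[float(a), float(b)] for a, b in intervals], **meta}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_intervals_json(path: str | Path) -> list[tuple[float, float]]:
    payload = json.loads(Path(path).read_text())
    return [tuple(iv) for iv in payload["intervals"]]


def write_annotations(ann: SpindleAnnotations, json_path: str | Path, tsv_path: str | Path | None = None):
    """Spindle annotations as JSON plus a BED-like per-channel TSV."""
    json_path = Path(json_path)
    payload = {
        "global_intervals": [[a, b] for a, b in ann.global_intervals],
        "peak_power": list(ann.peak_power),
        "channel_intervals": {c: [[a, b] for a, b in iv] for c, iv in ann.channel_intervals.items()},
        "params": ann.params,
        "duration_s": ann.duration_s,
    }
    json_path.write_text(json.dumps(payload, indent=1))
    if tsv_path is not None:
        rows = [
            {"channel": ch, "start_s": a, "end_s": b}
            for ch, ivs in ann.channel_intervals.items()
            for a, b in ivs
        ]
        pd.DataFrame(rows, columns=["channel", "start_s", "end_s"]).to_csv(
            tsv_path, sep="\t", index=False
        )
    return json_path


def read_annotations(json_path: str | Path) -> SpindleAnnotations:
    payload = json.loads(Path(json_path).read_text())
    return SpindleAnnotations(
        channel_intervals={
            c: [tuple(iv) for iv in ivs] for c, ivs in payload["channel_intervals"].items()
        },
        global_intervals=[tuple(iv) for iv in payload["global_intervals"]],
        peak_power=payload["peak_power"],
        params=payload["params"],
        duration_s=payload["duration_s"],
    )


def write_mask_tsv(mask, path: str | Path) -> Path:
    """Excluded-edge list as TSV (parcel_i, parcel_j, fidelity, threshold)."""
    path = Path(path)
    n = mask.n_parcels
    rows = [
        {
            "parcel_i": i,
            "parcel_j": j,
            "fidelity": mask.fidelity[i, j],
            "threshold": mask.threshold,
        }
        for i in range(n)
        for j in range(i + 1, n)
        if not mask.include[i, j]
    ]
    pd.DataFrame(rows, columns=["parcel_i", "parcel_j", "fidelity", "threshold"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Subject manifest CSV: subject_id, syndrome, neuro_1y, neuro_2y."""
    df = pd.read_csv(path)
    required = {"subject_id", "syndrome", "neuro_1y", "neuro_2y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad_syn = set(df["syndrome"]) - _SYNDROMES
    if bad_syn:
        raise ValueError(f"unknown syndrome labels: {sorted(bad_syn)}")
    for col in ("neuro_1y", "neuro_2y"):
        bad = set(df[col]) - _NEURO
        if bad:
            raise ValueError(f"unknown {col} labels: {sorted(bad)}")
    return df
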