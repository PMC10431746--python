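"""On-disk formats: HDF5 for arrays and geometry, CSV for tables, JSON for
ground truth and provenance sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import BandSpec, ConnectivityMap, SeedDefinition
from .containers import SensorRecording
from .mesh import SourceSpace
from .sensors import SensorArray


def save_recording(path: str | Path, rec: SensorRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("positions", data=rec.sensors.positions)
        f.create_dataset("orientations", data=rec.sensors.orientations)
        f.create_dataset("baselines", data=rec.sensors.baselines)
        f.create_dataset("types", data=np.array(
            [t.encode() for t in rec.sensors.types]))
        f.attrs["sfreq"] = rec.sfreq


def load_recording(path: str | Path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        sensors = SensorArray(
            positions=f["positions"][()],
            orientations=f["orientations"][()],
            types=np.array([t.decode() for t in f["types"][()]]),
            baselines=f["baselines"][()])
        return SensorRecording(f["data"][()], float(f.attrs["sfreq"]),
                               sensors)


def save_source_space(path: str | Path, space: SourceSpace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("vertices", data=space.vertices)
        f.create_dataset("triangles", data=space.triangles)
        f.create_dataset("normals", data=space.normals)


def load_source_space(path: str | Path) -> SourceSpace:
    with h5py.File(path, "r") as f:
        return SourceSpace(f["vertices"][()], f["triangles"][()],
                           f["normals"][()])


def save_matrix(path: str | Path, matrix: np.ndarray, name: str = "matrix",
                provenance: dict | None = None) -> None:
    """HDF5 matrix with an optional JSON provenance sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset(name, data=matrix)
    if provenance is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(provenance, indent=2, default=_jsonify))


def load_matrix(path: str | Path, name: str = "matrix") -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[name][()]


def save_connectivity_map(path: str | Path, cmap: ConnectivityMap) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=cmap.values)
    meta = {"band": {"name": cmap.band.name, "low_hz": cmap.band.low_hz,
                     "high_hz": cmap.band.high_hz},
            "seed_vertices": cmap.seed.vertices.tolist(),
            "n_epochs": cmap.n_epochs,
            "missing": cmap.missing.tolist()}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2))


def load_connectivity_map(path: str | Path) -> ConnectivityMap:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["values"][()]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    band = BandSpec(**meta["band"])
    return ConnectivityMap(values, band,
                           SeedDefinition(np.array(meta["seed_vertices"])),
                           meta["n_epochs"],
                           missing=np.array(meta["missing"], dtype=int))


def save_epochs(path: str | Path, epochs) -> None:
    from .containers import EpochSet  # local import avoids cycle at startup
    assert isinstance(epochs, EpochSet)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["tmin_ms"] = epochs.tmin_ms
        f.attrs["condition"] = epochs.condition
        f.attrs["kind"] = epochs.kind


def load_epochs(path: str | Path):
    from .containers import EpochSet
    with h5py.File(path, "r") as f:
        return EpochSet(f["data"][()], float(f.attrs["sfreq"]),
                        float(f.attrs["tmin_ms"]), str(f.attrs["condition"]),
                        kind=str(f.attrs["kind"]))


def save_events(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
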