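"""File formats: CSV for IMU streams and traces, HDF5 for waveform banks."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .samples import ImuStream, SpeechSample

__all__ = [
    "write_imu_csv",
    "read_imu_csv",
    "write_imu_h5",
    "read_imu_h5",
    "write_speech_bank",
    "read_speech_bank",
    "save_json",
    "load_json",
]


def write_imu_csv(path: str | Path, streams: dict[str, ImuStream] | ImuStream) -> None:
    if isinstance(streams, ImuStream):
        streams = {streams.sensor_id: streams}
    frames = [s.to_frame().assign(sensor_id=name) for name, s in streams.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_imu_csv(path: str | Path) -> dict[str, ImuStream]:
    df = pd.read_csv(path)
    return {
        str(sid): ImuStream.from_frame(g, sensor_id=str(sid))
        for sid, g in df.groupby("sensor_id")
    }


def write_imu_h5(path: str | Path, streams: dict[str, ImuStream]) -> None:
    with h5py.File(path, "w") as f:
        for name, s in streams.items():
            grp = f.create_group(name)
            grp.create_dataset("t", data=s.t)
            grp.create_dataset("accel", data=s.accel)
            grp.create_dataset("gyro", data=s.gyro)


def read_imu_h5(path: str | Path) -> dict[str, ImuStream]:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            grp = f[name]
            out[name] = ImuStream(
                t=grp["t"][...], accel=grp["accel"][...], gyro=grp["gyro"][...], sensor_id=name
            )
    return out


def write_speech_bank(path: str | Path, samples: list[SpeechSample]) -> None:
    """Store samples as HDF5 datasets (4 x T) with label/fs/seed attributes."""
    with h5py.File(path, "w") as f:
        for i, s in enumerate(samples):
            ds = f.create_dataset(f"sample_{i:06d}", data=s.data)
            ds.attrs["label"] = s.label
            ds.attrs["fs"] = s.fs
            if s.seed is not None:
                ds.attrs["seed"] = s.seed


def read_speech_bank(path: str | Path) -> list[SpeechSample]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            ds = f[key]
            out.append(
                SpeechSample(
                    data=ds[...],
                    label=str(ds.attrs["label"]),
                    fs=float(ds.attrs["fs"]),
                    seed=int(ds.attrs["seed"]) if "seed" in ds.attrs else None,
                )
            )
    return out


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
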