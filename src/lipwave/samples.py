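"""In-memory containers for raw IMU streams and 4-channel speech waveforms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: channel order used everywhere for speech waveforms
CHANNELS = ("theta_L", "gamma_L", "theta_C", "gamma_C")


@dataclass
class ImuStream:
    """Time-synchronized accelerometer (g) + gyroscope (deg/s) stream.

    ``t`` is seconds on a uniform grid; ``accel`` and ``gyro`` are (T, 3).
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sensor_id: str = "imu"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.shape != (self.t.size, 3) or self.gyro.shape != self.accel.shape:
            raise ValueError("ImuStream arrays must have shape (T,) / (T, 3)")

    @property
    def ts(self) -> float:
        """Sampling period (s)."""
        if self.t.size < 2:
            raise ValueError("need at least two samples to infer the period")
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.ts

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "ax": self.accel[:, 0],
                "ay": self.accel[:, 1],
                "az": self.accel[:, 2],
                "gx": self.gyro[:, 0],
                "gy": self.gyro[:, 1],
                "gz": self.gyro[:, 2],
                "sensor_id": self.sensor_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sensor_id: str | None = None) -> "ImuStream":
        if sensor_id is not None:
            df = df[df["sensor_id"] == sensor_id]
        elif "sensor_id" in df.columns:
            ids = df["sensor_id"].unique()
            if len(ids) != 1:
                raise ValueError(
                    f"frame holds sensors {list(ids)}; pass sensor_id explicitly"
                )
            sensor_id = str(ids[0])
        return cls(
            t=df["t"].to_numpy(),
            accel=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            sensor_id=sensor_id or "imu",
        )


@dataclass
class SpeechSample:
    """A 4-channel (theta_L, gamma_L, theta_C, gamma_C) waveform in degrees.

    ``data`` has shape (4, T); ``label`` is a word or sentence identifier.
    """

    data: np.ndarray
    label: str
    fs: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 4:
            raise ValueError("SpeechSample data must have shape (4, T)")

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.length / self.fs

    def copy(self, **overrides) -> "SpeechSample":
        kw = dict(data=self.data.copy(), label=self.label, fs=self.fs, seed=self.seed)
        kw.update(overrides)
        return SpeechSample(**kw)
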