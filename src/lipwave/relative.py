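"""Misalignment calibration and relative lip/chin motion extraction.

The mounting rotation between each sensor case and its body segment is
estimated from two quasi-static postures (upright, lean-forward): the
phase-1 gravity direction fixes the body z axis in sensor coordinates, and
the lean rotation axis (z x phase-2 gravity, pointing left) fixes the body y
axis.  After alignment, the three fused absolute attitudes are composed into
relative lip/chin-versus-head attitudes and angular velocities, which cancels
head-motion interference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion import DEG, FusionParams, rotation_from_attitude, run_filter
from .samples import ImuStream

__all__ = [
    "CalibrationResult",
    "calibrate_misalignment",
    "relative_rotation",
    "relative_attitude",
    "relative_angular_velocity",
    "process_session",
]

SENSORS = ("head", "lip", "chin")


@dataclass
class CalibrationResult:
    """Sensor-to-body rotations (proper orthonormal) with residuals (deg).

    ``rotations[s] @ raw_vector`` expresses a sensor-frame vector in the
    body frame of segment ``s``.  The residual is the out-of-sagittal-plane
    angle of the aligned phase-2 gravity (0 for a perfect two-posture pair).
    """

    rotations: dict[str, np.ndarray]
    residuals_deg: dict[str, float]

    def __post_init__(self) -> None:
        for name, r in self.rotations.items():
            if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or not np.isclose(
                np.linalg.det(r), 1.0, atol=1e-6
            ):
                raise ValueError(f"rotation for {name!r} is not proper orthonormal")


def _static_mean_gravity(stream: ImuStream, still_thresh_deg_s: float = 3.0) -> np.ndarray:
    gyro_norm = np.linalg.norm(stream.gyro, axis=1)
    if np.mean(gyro_norm) > still_thresh_deg_s:
        raise ValueError(
            f"phase not static: mean gyro norm {np.mean(gyro_norm):.2f} deg/s"
        )
    return stream.accel.mean(axis=0)


def _align_from_two_postures(v1: np.ndarray, v2: np.ndarray, min_sep_deg: float) -> tuple[np.ndarray, float]:
    """Sensor->body rotation from the two phase gravity directions."""
    z_b = v1 / np.linalg.norm(v1)
    u2 = v2 / np.linalg.norm(v2)
    sep = np.degrees(np.arccos(np.clip(z_b @ u2, -1.0, 1.0)))
    if sep < min_sep_deg:
        raise ValueError(
            f"phases nearly collinear ({sep:.1f} deg apart): no lean detected"
        )
    y_b = np.cross(z_b, u2)
    y_b /= np.linalg.norm(y_b)
    x_b = np.cross(y_b, z_b)
    rot = np.vstack([x_b, y_b, z_b])
    residual = abs(90.0 - np.degrees(np.arccos(np.clip((rot @ u2) @ np.array([0.0, 1.0, 0.0]), -1, 1))))
    return rot, float(residual)


def calibrate_misalignment(
    phase1: dict[str, ImuStream],
    phase2: dict[str, ImuStream],
    min_separation_deg: float = 10.0,
    still_thresh_deg_s: float = 3.0,
) -> CalibrationResult:
    """Two-posture mounting calibration for the head, lip and chin sensors.

    Phase 1 is recorded standing upright, phase 2 leaning forward, both for
    a few seconds with the mouth closed (a stillness check on the gyroscope
    guards the posture requirement).  Leaning forward rotates gravity about
    the leftward body y axis, which the construction exploits:
    z_b = unit(mean phase-1 accel), y_b = unit(z_b x mean phase-2 accel),
    x_b = y_b x z_b.
    """
    rotations: dict[str, np.ndarray] = {}
    residuals: dict[str, float] = {}
    for name in phase1:
        if name not in phase2:
            raise KeyError(f"sensor {name!r} missing from phase 2")
        v1 = _static_mean_gravity(phase1[name], still_thresh_deg_s)
        v2 = _static_mean_gravity(phase2[name], still_thresh_deg_s)
        rotations[name], residuals[name] = _align_from_two_postures(
            v1, v2, min_separation_deg
        )
    return CalibrationResult(rotations=rotations, residuals_deg=residuals)


def relative_rotation(m_nb_head: np.ndarray, m_nb_other: np.ndarray) -> np.ndarray:
    """Rotation from the head body frame to the lip/chin body frame."""
    return np.linalg.inv(m_nb_head) @ m_nb_other


def relative_attitude(m_rel: np.ndarray) -> tuple[float, float]:
    """Relative pitch/roll (deg) from a relative rotation matrix.

    theta = -atan(M[0,2] / M[0,0]); gamma = -atan(M[2,1] / M[1,1]).
    """
    if m_rel[0, 0] == 0 or m_rel[1, 1] == 0:
        raise ValueError("degenerate pose: zero denominator in attitude extraction")
    theta = -np.arctan(m_rel[0, 2] / m_rel[0, 0])
    gamma = -np.arctan(m_rel[2, 1] / m_rel[1, 1])
    return float(theta / DEG), float(gamma / DEG)


def relative_angular_velocity(
    omega_head_b: np.ndarray,
    omega_other_b: np.ndarray,
    m_nb_head: np.ndarray,
    m_nb_other: np.ndarray,
) -> np.ndarray:
    """omega_rel = M_nb_head @ inv(M_nb_other) @ omega_other - omega_head."""
    return m_nb_head @ np.linalg.inv(m_nb_other) @ np.asarray(omega_other_b, float) - np.asarray(
        omega_head_b, float
    )


def process_session(
    streams: dict[str, ImuStream],
    calib: CalibrationResult | None = None,
    params: FusionParams | None = None,
) -> pd.DataFrame:
    """Full pipeline for one recording: align, fuse, compose relative motion.

    Returns a frame with columns t, theta_L, gamma_L, theta_C, gamma_C (deg),
    omega_L_{x,y,z}, omega_C_{x,y,z} (deg/s) and the head absolute attitude
    for diagnostics.  Head rotation common to all sensors cancels in the
    relative channels.
    """
    for name in SENSORS:
        if name not in streams:
            raise KeyError(f"missing sensor stream {name!r}")
    lengths = {len(streams[s]) for s in SENSORS}
    if len(lengths) != 1:
        raise ValueError("sensor streams have mismatched lengths")
    ts_vals = {round(streams[s].ts, 9) for s in SENSORS}
    if len(ts_vals) != 1:
        raise ValueError("sensor streams have mismatched sampling periods")
    p = params or FusionParams(ts=streams["head"].ts)

    aligned: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in SENSORS:
        s = streams[name]
        r = calib.rotations[name] if calib is not None else np.eye(3)
        aligned[name] = (s.accel @ r.T, s.gyro @ r.T)

    att = {}
    for name in SENSORS:
        accel, gyro = aligned[name]
        att[name], _ = run_filter(accel, gyro, p)

    n = len(streams["head"])
    cols = {
        "t": streams["head"].t,
        "theta_L": np.empty(n),
        "gamma_L": np.empty(n),
        "theta_C": np.empty(n),
        "gamma_C": np.empty(n),
    }
    for key in ("omega_L", "omega_C"):
        for ax in "xyz":
            cols[f"{key}_{ax}"] = np.empty(n)
    cols["theta_H_abs"] = att["head"][:, 0]
    cols["gamma_H_abs"] = att["head"][:, 1]

    mats = {
        name: np.stack(
            [rotation_from_attitude(a[0], a[1]) for a in att[name]]
        )
        for name in SENSORS
    }
    for i in range(n):
        m_head = mats["head"][i]
        for other, tag in (("lip", "L"), ("chin", "C")):
            m_rel = relative_rotation(m_head, mats[other][i])
            theta, gamma = relative_attitude(m_rel)
            cols[f"theta_{tag}"][i] = theta
            cols[f"gamma_{tag}"][i] = gamma
            w = relative_angular_velocity(
                aligned["head"][1][i], aligned[other][1][i], m_head, mats[other][i]
            )
            for j, ax in enumerate("xyz"):
                cols[f"omega_{tag}_{ax}"][i] = w[j]
    return pd.DataFrame(cols)
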