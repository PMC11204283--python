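"""Seeded synthetic-motion generator.

Everything the wearable hardware would record is emulated here: rigid-body
head/lip/chin rotations observed through misaligned, noisy IMUs, and
stylized per-word 4-channel speech waveforms with within-word variability.
The templates are smooth band-limited stand-ins for articulator motion, not
claims about real articulation morphology.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .fusion import DEG, rotation_from_attitude, skew
from .samples import ImuStream, SpeechSample
from .synthesis import SynthesisConfig, concatenate_words, segment_word, smooth_transitions

__all__ = [
    "RigidTrajectory",
    "SensorModel",
    "WordTemplate",
    "simulate_imu_stream",
    "make_turntable_trajectory",
    "make_word_template",
    "sample_word",
    "make_ground_truth_sentence",
    "random_misalignment",
]


@dataclass
class RigidTrajectory:
    """Ground-truth motion of one body segment on a uniform time grid.

    ``theta``/``gamma`` are pitch/roll in degrees, ``omega_b`` the body-frame
    angular velocity (deg/s) consistent with the attitude derivative, and
    ``accel_b`` the body-frame linear acceleration in g units.
    """

    t: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray
    omega_b: np.ndarray
    accel_b: np.ndarray
    dwell_mask: np.ndarray | None = None
    dwell_angles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        dt = np.diff(self.t)
        if self.t.size < 2 or not np.all(dt > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid must have a constant step")

    @property
    def ts(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size

    def attitude_matrices(self) -> np.ndarray:
        """Stack of M_nb(t), shape (T, 3, 3)."""
        return np.stack(
            [rotation_from_attitude(th, ga) for th, ga in zip(self.theta, self.gamma)]
        )

    @classmethod
    def from_angles(
        cls,
        t: np.ndarray,
        theta_deg: np.ndarray,
        gamma_deg: np.ndarray,
        accel_b: np.ndarray | None = None,
        **extra,
    ) -> "RigidTrajectory":
        """Build a trajectory from angle curves, deriving omega_b.

        The body rate is extracted from central differences of M_nb via
        [omega x] = -dM/dt @ M^T, which keeps it consistent with the gravity
        propagation model used by the fusion filter.
        """
        t = np.asarray(t, dtype=float)
        mats = np.stack(
            [rotation_from_attitude(th, ga) for th, ga in zip(theta_deg, gamma_deg)]
        )
        dt = t[1] - t[0]
        dmats = np.gradient(mats, dt, axis=0)
        omega = np.empty((t.size, 3))
        for i in range(t.size):
            w = -dmats[i] @ mats[i].T
            w = 0.5 * (w - w.T)  # project onto skew-symmetric part
            omega[i] = np.array([w[2, 1], w[0, 2], w[1, 0]]) / DEG
        if accel_b is None:
            accel_b = np.zeros((t.size, 3))
        return cls(
            t=t,
            theta=np.asarray(theta_deg, dtype=float),
            gamma=np.asarray(gamma_deg, dtype=float),
            omega_b=omega,
            accel_b=np.asarray(accel_b, dtype=float),
            **extra,
        )


@dataclass
class SensorModel:
    """IMU observation model: fixed mounting misalignment plus white noise.

    ``misalignment`` rotates body-frame vectors into the sensor case frame.
    Outputs are clipped to the hardware ranges (+/-2 g, +/-200 deg/s).
    """

    misalignment: np.ndarray = field(default_factory=lambda: np.eye(3))
    sigma_v: float = 5e-3
    sigma_g: float = 0.1
    accel_range: float = 2.0
    gyro_range: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.misalignment, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-8
        ):
            raise ValueError("misalignment must be a proper rotation matrix")
        self.misalignment = r


def random_misalignment(rng: np.random.Generator, max_angle_deg: float = 30.0) -> np.ndarray:
    """Random mounting rotation with angle uniform in (0, max_angle_deg]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.2, 1.0) * max_angle_deg * DEG
    return Rotation.from_rotvec(angle * axis).as_matrix()


def simulate_imu_stream(
    trajectory: RigidTrajectory, sensor: SensorModel, sensor_id: str = "imu"
) -> ImuStream:
    """Observe a rigid trajectory through an IMU.

    Accelerometer: f = R_mis @ (g_b - a_b) + noise, with g_b = M_nb @ e_z
    (reaction-force convention, so a resting sensor reads +1 g on z).
    Gyroscope: R_mis @ omega_b + noise.  Both clipped to the sensor range.
    """
    rng = np.random.default_rng(sensor.seed)
    mats = trajectory.attitude_matrices()
    g_b = mats @ np.array([0.0, 0.0, 1.0])
    f_body = g_b - trajectory.accel_b
    accel = f_body @ sensor.misalignment.T
    gyro = trajectory.omega_b @ sensor.misalignment.T
    if sensor.sigma_v > 0:
        accel = accel + rng.normal(scale=sensor.sigma_v, size=accel.shape)
    if sensor.sigma_g > 0:
        gyro = gyro + rng.normal(scale=sensor.sigma_g, size=gyro.shape)
    accel = np.clip(accel, -sensor.accel_range, sensor.accel_range)
    gyro = np.clip(gyro, -sensor.gyro_range, sensor.gyro_range)
    return ImuStream(t=trajectory.t, accel=accel, gyro=gyro, sensor_id=sensor_id)


def make_turntable_trajectory(
    axis: str = "y",
    sweep: tuple[float, float] = (-60.0, 60.0),
    step: float = 15.0,
    dwell_s: float = 2.0,
    ramp_s: float = 0.5,
    fs: float = 100.0,
) -> RigidTrajectory:
    """Dwell-and-rotate calibration sweep, like a single-axis turntable run.

    ``axis='y'`` sweeps pitch, ``axis='x'`` sweeps roll.  Each commanded
    angle is held for ``dwell_s`` (long enough for the fusion filter to
    settle); plateaus are joined by smooth cosine ramps.  ``dwell_mask``
    marks on-plateau samples and ``dwell_angles`` the commanded angles.
    """
    lo, hi = sweep
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi or abs(lo) > 60 or abs(hi) > 60:
        raise ValueError("sweep must lie within +/-60 degrees")
    angles = np.arange(lo, hi + 0.5 * step, step)
    if angles.size == 0:
        raise ValueError("empty sweep")
    n_dwell = int(round(dwell_s * fs))
    n_ramp = int(round(ramp_s * fs))
    curve: list[np.ndarray] = []
    mask: list[np.ndarray] = []
    for i, ang in enumerate(angles):
        if i > 0:
            prev = angles[i - 1]
            s = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_ramp, endpoint=False)))
            curve.append(prev + (ang - prev) * s)
            mask.append(np.zeros(n_ramp, dtype=bool))
        curve.append(np.full(n_dwell, ang))
        mask.append(np.ones(n_dwell, dtype=bool))
    angle = np.concatenate(curve)
    dwell_mask = np.concatenate(mask)
    t = np.arange(angle.size) / fs
    zeros = np.zeros_like(angle)
    theta, gamma = (angle, zeros) if axis == "y" else (zeros, angle)
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    return RigidTrajectory.from_angles(
        t, theta, gamma, dwell_mask=dwell_mask, dwell_angles=angles
    )


def static_trajectory(
    duration_s: float, fs: float = 100.0, theta: float = 0.0, gamma: float = 0.0
) -> RigidTrajectory:
    """Constant-attitude trajectory (calibration phases, rest segments)."""
    n = max(2, int(round(duration_s * fs)))
    t = np.arange(n) / fs
    return RigidTrajectory.from_angles(t, np.full(n, theta), np.full(n, gamma))


@dataclass
class WordTemplate:
    """Nominal 4-channel waveform of one word (degrees), with rest margins."""

    word_id: str
    waveform: np.ndarray
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 2 or self.waveform.shape[0] != 4:
            raise ValueError("template waveform must have shape (4, T)")
        if np.max(np.abs(self.waveform)) > 60.0:
            raise ValueError("template exceeds the +/-60 deg articulation range")

    @property
    def length(self) -> int:
        return self.waveform.shape[1]


def _stable_id(name: str) -> int:
    """Process-independent 31-bit hash of an identifier (seeding)."""
    return zlib.crc32(name.encode()) % 2**31


def make_word_template(
    word_id: str,
    nominal_length: int = 100,
    seed: int = 0,
    fs: float = 100.0,
    amplitude_deg: float = 40.0,
) -> WordTemplate:
    """Generate a smooth, band-limited, speech-like word template.

    Each channel is a sum of 3-6 random Gaussian bumps, windowed to rest at
    both ends, low-passed below 8 Hz and capped at ``amplitude_deg`` (inside
    the +/-60 deg validated articulation range).  Deterministic per seed.
    """
    if nominal_length < 60:
        raise ValueError("words last >= 0.6 s at 100 Hz: need >= 60 samples")
    rng = np.random.default_rng(np.random.SeedSequence([_stable_id(word_id), seed]))
    n = nominal_length
    x = np.arange(n)
    wave = np.zeros((4, n))
    for ch in range(4):
        n_bumps = rng.integers(3, 7)
        # articulation begins promptly at word onset: bumps span nearly the
        # whole duration, leaving only a short rest shoulder at each end
        centers = rng.uniform(0.08, 0.92, size=n_bumps) * n
        widths = rng.uniform(0.05, 0.12, size=n_bumps) * n
        widths = np.clip(widths, 5.0, None)  # keep energy below 8 Hz
        amps = rng.uniform(-1.0, 1.0, size=n_bumps)
        for c, w, a in zip(centers, widths, amps):
            wave[ch] += a * np.exp(-0.5 * ((x - c) / w) ** 2)
    # short envelope bringing the endpoints to rest
    edge = 6
    env = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, edge)))
    env[:edge] = ramp
    env[-edge:] = ramp[::-1]
    wave *= env
    b, a = butter(4, 8.0 / (fs / 2), btype="low")
    wave = filtfilt(b, a, wave, axis=1)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= amplitude_deg * rng.uniform(0.6, 1.0) / peak
    return WordTemplate(word_id=word_id, waveform=wave, fs=fs, seed=seed)


def _rescale_length(wave: np.ndarray, factor: float) -> np.ndarray:
    """Time-rescale a (4, T) waveform by linear interpolation."""
    n = wave.shape[1]
    m = max(2, int(round(n * factor)))
    old = np.linspace(0.0, 1.0, n)
    new = np.linspace(0.0, 1.0, m)
    return np.stack([np.interp(new, old, wave[ch]) for ch in range(4)])


def sample_word(
    template: WordTemplate,
    n: int = 20,
    length_sd: float = 0.1,
    amp_sd: float = 0.1,
    seed: int = 0,
) -> list[SpeechSample]:
    """Draw word repetitions with natural length/amplitude variability.

    Each repetition rescales the template duration by a factor ~ N(1,
    length_sd) (truncated positive) via linear interpolation and scales its
    amplitude by an independent N(1, amp_sd) factor.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if length_sd < 0 or amp_sd < 0:
        raise ValueError("SDs must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([template.seed, seed, 7]))
    out = []
    for _ in range(n):
        lf = _truncated_normal(rng, 1.0, length_sd)
        af = _truncated_normal(rng, 1.0, amp_sd)
        wave = _rescale_length(template.waveform, lf) * af
        out.append(SpeechSample(data=wave, label=template.word_id, fs=template.fs))
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to strictly positive values."""
    if sd == 0:
        return mean
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0.05:
            return v
    return 0.05


def make_ground_truth_sentence(
    word_samples: list[SpeechSample],
    true_params: list[tuple[float, float]],
    jitter_sd: float = 0.0,
    seed: int = 0,
    config: SynthesisConfig | None = None,
) -> SpeechSample:
    """Stand-in for an actually spoken sentence with known segmentation.

    Applies independent per-word length/amplitude jitter, trims each word by
    its true (r_l, r_e) pair, concatenates, and low-pass smooths -- the same
    segment-concatenate-smooth chain used for synthesis, so that the
    segmentation-parameter optimizer can attempt to recover ``true_params``.
    """
    if len(word_samples) != len(true_params):
        raise ValueError("need one (r_l, r_e) pair per word")
    cfg = config or SynthesisConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    trimmed = []
    for sample, (r_l, r_e) in zip(word_samples, true_params):
        if r_l < 0 or r_e < 0 or r_l + r_e > 1:
            raise ValueError("segmentation pair violates r_l + r_e <= 1")
        s = sample
        if jitter_sd > 0:
            lf = _truncated_normal(rng, 1.0, jitter_sd)
            af = _truncated_normal(rng, 1.0, jitter_sd)
            s = sample.copy(data=_rescale_length(sample.data, lf) * af)
        trimmed.append(segment_word(s, r_l, r_e))
    draft = concatenate_words(trimmed)
    return smooth_transitions(draft, cfg)
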