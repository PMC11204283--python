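"""Kalman-filter attitude fusion for a single IMU.

Each sensor's absolute pitch/roll is estimated from its tri-axial
accelerometer and gyroscope by a 6-state Kalman filter whose state is the
linear acceleration ``a_b`` and the gravity direction ``g_b``, both expressed
in the sensor's body frame.  Linear acceleration follows a first-order
Gauss-Markov prior ``da/dt = eta * a + w``; gravity is propagated with the
gyroscope through ``dg/dt = -[omega x] g``.  The accelerometer observation is
``f = g_b - a_b + noise`` (reaction-force convention: a resting sensor reads
+1 g along body z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEG = np.pi / 180.0

__all__ = [
    "FusionParams",
    "KalmanState",
    "skew",
    "rotation_from_attitude",
    "attitude_from_gravity",
    "build_transition",
    "kalman_step",
    "init_state",
    "run_filter",
]


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix [v x] such that skew(v) @ u == cross(v, u)."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rotation_from_attitude(theta_deg: float, gamma_deg: float) -> np.ndarray:
    """Rotation matrix M_nb from the navigation frame to the body frame.

    Parameters are pitch ``theta`` and roll ``gamma`` in degrees; heading is
    ignored (the interface only resolves motion in the sagittal/frontal
    planes).  ``M_nb @ [0, 0, 1]`` is the gravity direction in body axes.
    """
    th = theta_deg * DEG
    ga = gamma_deg * DEG
    ct, st = np.cos(th), np.sin(th)
    cg, sg = np.cos(ga), np.sin(ga)
    return np.array(
        [
            [ct, 0.0, -st],
            [sg * st, cg, sg * ct],
            [cg * st, -sg, cg * ct],
        ]
    )


def attitude_from_gravity(g_b: np.ndarray) -> tuple[float, float]:
    """Pitch/roll (deg) from a body-frame gravity vector.

    gamma = atan(g_y / g_z); theta = -atan(g_x * cos(gamma) / g_z).
    Both angles live in (-90, 90) degrees.  Raises for g_z == 0 (gimbal
    degenerate pose) or a zero vector.
    """
    g_b = np.asarray(g_b, dtype=float)
    if not np.linalg.norm(g_b) > 0:
        raise ValueError("gravity vector has zero norm")
    gx, gy, gz = g_b
    if gz == 0:
        raise ValueError("g_z = 0: attitude undefined at +/-90 deg")
    gamma = np.arctan(gy / gz)
    theta = -np.arctan(gx * np.cos(gamma) / gz)
    return float(theta / DEG), float(gamma / DEG)


@dataclass
class FusionParams:
    """Tunables of the fusion filter.

    ``eta`` is the Gauss-Markov constant (1/s, must be <= 0 for a stable
    acceleration prior; default -2.0, i.e. 0.5 s correlation time).
    ``sigma_a`` (g) and ``sigma_g`` (deg/s) are the process SDs of the
    acceleration and gyroscope noise; ``sigma_v`` (g) is the accelerometer
    measurement SD.  ``n_init`` accelerometer samples seed the gravity state.
    """

    ts: float = 0.01
    eta: float = -2.0
    sigma_a: float = 0.05
    sigma_g: float = 0.1
    sigma_v: float = 5e-3
    p0: float = 0.01
    n_init: int = 50

    def __post_init__(self) -> None:
        if self.ts <= 0:
            raise ValueError("sampling period must be positive")
        if self.eta > 0:
            raise ValueError("eta must be <= 0 for a stable GM prior")
        if min(self.sigma_a, self.sigma_g, self.sigma_v) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class KalmanState:
    """Filter state: x = [a_b, g_b] (g units) with covariance P (6x6)."""

    x: np.ndarray
    p: np.ndarray
    k_gain: np.ndarray | None = None
    iteration: int = 0

    @property
    def a_b(self) -> np.ndarray:
        return self.x[:3]

    @property
    def g_b(self) -> np.ndarray:
        return self.x[3:]


_C = np.hstack([-np.eye(3), np.eye(3)])  # observation: f = g_b - a_b


def _rodrigues(omega_rad: np.ndarray, ts: float) -> np.ndarray:
    """Closed-form matrix exponential expm(-[omega x] * ts)."""
    ang = np.linalg.norm(omega_rad) * ts
    if ang < 1e-12:
        return np.eye(3)
    axis = omega_rad / np.linalg.norm(omega_rad)
    k = skew(axis)
    # expm(-[w x] t) = I - sin(ang) K + (1 - cos(ang)) K^2
    return np.eye(3) - np.sin(ang) * k + (1.0 - np.cos(ang)) * (k @ k)


def build_transition(
    omega_deg_s: np.ndarray, params: FusionParams, g_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete transition Phi and process covariance Q for one step.

    Phi = blockdiag(exp(eta*Ts)*I3, expm(-[omega x]*Ts)); the gravity block
    is the exact Rodrigues form, not a truncated series.  Q couples the
    gyroscope noise into the gravity states through [g x][g x]^T evaluated at
    the current gravity estimate.
    """
    omega = np.asarray(omega_deg_s, dtype=float) * DEG
    if not np.all(np.isfinite(omega)):
        raise ValueError("non-finite angular rate")
    phi = np.zeros((6, 6))
    phi[:3, :3] = np.exp(params.eta * params.ts) * np.eye(3)
    phi[3:, 3:] = _rodrigues(omega, params.ts)
    gx = skew(np.asarray(g_b, dtype=float))
    q = np.zeros((6, 6))
    q[:3, :3] = (params.sigma_a * params.ts) ** 2 * np.eye(3)
    q[3:, 3:] = (params.sigma_g * DEG * params.ts) ** 2 * (gx @ gx.T)
    return phi, q


def kalman_step(
    state: KalmanState,
    accel_g: np.ndarray,
    gyro_deg_s: np.ndarray,
    params: FusionParams,
) -> KalmanState:
    """One predict/update cycle.

    Predict with the gyro-driven transition, then correct with the
    accelerometer reading through C = [-I3  I3] and R = sigma_v^2 * I3.
    """
    phi, q = build_transition(gyro_deg_s, params, state.g_b)
    x_pred = phi @ state.x
    p_pred = phi @ state.p @ phi.T + q
    r = params.sigma_v**2 * np.eye(3)
    s = _C @ p_pred @ _C.T + r
    try:
        k = np.linalg.solve(s.T, (_C @ p_pred.T)).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate cfg
        raise ValueError("singular innovation covariance") from exc
    innov = np.asarray(accel_g, dtype=float) - _C @ x_pred
    x_new = x_pred + k @ innov
    ikc = np.eye(6) - k @ _C
    # Joseph form keeps P symmetric PSD over long runs
    p_new = ikc @ p_pred @ ikc.T + k @ r @ k.T
    p_new = 0.5 * (p_new + p_new.T)
    return KalmanState(x=x_new, p=p_new, k_gain=k, iteration=state.iteration + 1)


def init_state(accel_g: np.ndarray, params: FusionParams) -> KalmanState:
    """Initialise from the first samples: g_b = mean accel, a_b = 0."""
    accel_g = np.atleast_2d(np.asarray(accel_g, dtype=float))
    n = min(params.n_init, accel_g.shape[0])
    g0 = accel_g[:n].mean(axis=0)
    x = np.concatenate([np.zeros(3), g0])
    return KalmanState(x=x, p=params.p0 * np.eye(6))


def run_filter(
    accel_g: np.ndarray,
    gyro_deg_s: np.ndarray,
    params: FusionParams,
    state: KalmanState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Filter a whole stream; returns (attitude [T,2] deg, gravity [T,3] g).

    Attitude columns are (theta, gamma).  A fresh state is seeded from the
    first ``n_init`` accelerometer samples unless one is supplied.
    """
    accel_g = np.asarray(accel_g, dtype=float)
    gyro_deg_s = np.asarray(gyro_deg_s, dtype=float)
    if accel_g.shape != gyro_deg_s.shape or accel_g.ndim != 2:
        raise ValueError("accel and gyro streams must share shape (T, 3)")
    if state is None:
        state = init_state(accel_g, params)
    n = accel_g.shape[0]
    att = np.empty((n, 2))
    grav = np.empty((n, 3))
    for i in range(n):
        state = kalman_step(state, accel_g[i], gyro_deg_s[i], params)
        grav[i] = state.g_b
        theta, gamma = attitude_from_gravity(state.g_b)
        att[i, 0] = theta
        att[i, 1] = gamma
    return att, grav
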