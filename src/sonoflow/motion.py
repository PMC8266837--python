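"""Transducer attitude estimation from the probe-mounted IMU.

A gradient-descent complementary AHRS (attitude and heading reference
system) fuses the 100 Hz gyroscope, accelerometer and magnetometer streams
into an absolute sensor-to-world orientation, from which the world-frame
linear acceleration of the transducer is recovered by removing gravity.

Conventions
-----------
* World frame: z up, gravity vector ``(0, 0, -9.81)`` m/s^2; the magnetic
  reference is horizontal along +x (no inclination).
* Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, and map sensor
  coordinates to world coordinates.
* The accelerometer measures specific force (it reads ``+9.81`` along the
  sensor axis pointing up when stationary), so world linear acceleration is
  ``R(q) a_sensor + (0, 0, -9.81)``.

Each update propagates the quaternion with the gyro rate and applies a
correction step of magnitude ``gain`` (rad/s of quaternion rate) along the
normalized negative gradient of the gravity+magnetic alignment error —
the standard gradient-descent filter formulation.  ``gain = 0`` degenerates
to pure gyro integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

GRAVITY = np.array([0.0, 0.0, -9.81])
GRAVITY_REF = np.array([0.0, 0.0, 1.0])   # unit "up" in the world frame
MAG_REF = np.array([1.0, 0.0, 0.0])
DEFAULT_GAIN = 0.1


@dataclass(frozen=True)
class OrientationState:
    """Unit sensor-to-world attitude quaternion at time t."""

    q: np.ndarray  # (4,), scalar-first, unit norm
    t: float


@dataclass
class OrientationTrajectory:
    """Per-sample attitude and world-frame linear acceleration."""

    t: np.ndarray        # (N,)
    quats: np.ndarray    # (N, 4) scalar-first, unit norm
    linacc: np.ndarray   # (N, 3) m/s^2, world frame


# -- quaternion primitives (Hamilton, scalar-first) -------------------------


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate a sensor-frame vector into the world frame."""
    w, u = q[0], q[1:]
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def quat_rotate_inv(q: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Rotate a world-frame vector into the sensor frame."""
    w, u = q[0], q[1:]
    ud = np.cross(u, d)
    return d - 2.0 * w * ud + 2.0 * np.cross(u, np.cross(u, d))


def quat_angle_deg(p: np.ndarray, q: np.ndarray) -> float:
    """Geodesic angle between two attitudes, degrees."""
    dot = abs(float(np.dot(p, q)))
    return float(np.degrees(2.0 * np.arccos(min(1.0, dot))))


def _alignment_gradient(q: np.ndarray, a_hat: np.ndarray, m_hat: np.ndarray | None) -> np.ndarray:
    """Gradient (J^T f) of the gravity+magnetic alignment error w.r.t. q.

    The objective stacks the residuals ``R(q)^T (0,0,1) - a_hat`` and
    ``R(q)^T (1,0,0) - m_hat``; both Jacobians have closed forms in the
    quaternion components (the standard gradient-descent AHRS equations for
    a z-up gravity reference and a horizontal +x magnetic reference).
    """
    w, x, y, z = q
    # gravity residual: R^T e_z = (2(xz - wy), 2(yz + wx), 1 - 2(x^2 + y^2))
    fg = np.array(
        [2.0 * (x * z - w * y), 2.0 * (y * z + w * x), 1.0 - 2.0 * (x * x + y * y)]
    ) - a_hat
    grad = np.array(
        [
            -2.0 * y * fg[0] + 2.0 * x * fg[1],
            2.0 * z * fg[0] + 2.0 * w * fg[1] - 4.0 * x * fg[2],
            -2.0 * w * fg[0] + 2.0 * z * fg[1] - 4.0 * y * fg[2],
            2.0 * x * fg[0] + 2.0 * y * fg[1],
        ]
    )
    if m_hat is not None:
        # magnetic residual: R^T e_x = (1 - 2(y^2 + z^2), 2(xy - wz), 2(xz + wy))
        fm = np.array(
            [1.0 - 2.0 * (y * y + z * z), 2.0 * (x * y - w * z), 2.0 * (x * z + w * y)]
        ) - m_hat
        grad += np.array(
            [
                -2.0 * z * fm[1] + 2.0 * y * fm[2],
                2.0 * y * fm[1] + 2.0 * z * fm[2],
                -4.0 * y * fm[0] + 2.0 * x * fm[1] + 2.0 * w * fm[2],
                -4.0 * z * fm[0] - 2.0 * w * fm[1] + 2.0 * x * fm[2],
            ]
        )
    return grad


def ahrs_update(
    state: OrientationState,
    gyro: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray,
    dt: float,
    gain: float = DEFAULT_GAIN,
) -> OrientationState:
    """One fusion step: gyro propagation plus gravity/magnetic correction.

    The correction is a unit-normalized gradient step on the squared
    alignment error of the measured (normalized) accelerometer and
    magnetometer against the world gravity and magnetic references, scaled
    by ``gain``.  With zero-norm accelerometer input (free fall) the
    correction is skipped and the update is gyro-only.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = state.q
    omega = np.asarray(gyro, dtype=float)
    # predict with the gyro rate, then correct at the predicted attitude so
    # the vector measurements (taken at the end of the interval) are
    # compared against the state they actually correspond to
    q_pred = quat_normalize(q + 0.5 * quat_multiply(q, np.array([0.0, *omega])) * dt)

    a_norm = np.linalg.norm(accel)
    if gain > 0 and a_norm > 0:
        a_hat = np.asarray(accel, dtype=float) / a_norm
        m_norm = np.linalg.norm(mag)
        m_hat = np.asarray(mag, dtype=float) / m_norm if m_norm > 0 else None
        grad = _alignment_gradient(q_pred, a_hat, m_hat)
        g_norm = np.linalg.norm(grad)
        if g_norm > 0:
            q_pred = quat_normalize(q_pred - gain * dt * grad / g_norm)

    return OrientationState(q_pred, state.t + dt)


def triad_init(accel: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Initial attitude from a single accelerometer/magnetometer pair.

    The measured specific force fixes the world up axis, the horizontal
    component of the magnetic field fixes world x (TRIAD construction).
    """
    z = np.asarray(accel, dtype=float)
    nz = np.linalg.norm(z)
    if nz == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    z = z / nz
    m = np.asarray(mag, dtype=float)
    x = m - (m @ z) * z
    nx = np.linalg.norm(x)
    if nx == 0:  # magnetic field parallel to gravity: heading unobservable
        x = np.array([1.0, 0.0, 0.0]) - z[0] * z
        x = x / np.linalg.norm(x)
    else:
        x = x / nx
    y = np.cross(z, x)
    rot = np.vstack([x, y, z])  # world axes expressed in sensor coordinates
    from scipy.spatial.transform import Rotation

    xyzw = Rotation.from_matrix(rot).as_quat()
    q = np.array([xyzw[3], xyzw[0], xyzw[1], xyzw[2]])
    return q if q[0] >= 0 else -q


def fuse_stream(imu: pd.DataFrame, gain: float = DEFAULT_GAIN) -> OrientationTrajectory:
    """Run the AHRS over a whole IMU stream.

    Parameters
    ----------
    imu
        DataFrame with columns ``t, gx, gy, gz, ax, ay, az, mx, my, mz``
        (strictly increasing timestamps, at least two samples).
    gain
        Correction step magnitude; 0 gives pure gyro integration.
    """
    if len(imu) < 2:
        raise ValueError("at least two IMU samples are required")
    t = imu["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("IMU timestamps must be strictly increasing")
    gyro = imu[["gx", "gy", "gz"]].to_numpy(dtype=float)
    accel = imu[["ax", "ay", "az"]].to_numpy(dtype=float)
    mag = imu[["mx", "my", "mz"]].to_numpy(dtype=float)

    n = len(t)
    quats = np.empty((n, 4))
    quats[0] = triad_init(accel[0], mag[0])
    state = OrientationState(quats[0], float(t[0]))
    for i in range(1, n):
        state = ahrs_update(state, gyro[i - 1], accel[i], mag[i], float(t[i] - t[i - 1]), gain)
        quats[i] = state.q

    from scipy.spatial.transform import Rotation

    xyzw = np.column_stack([quats[:, 1], quats[:, 2], quats[:, 3], quats[:, 0]])
    linacc = Rotation.from_quat(xyzw).apply(accel) + GRAVITY
    return OrientationTrajectory(t=t, quats=quats, linacc=linacc)


def trajectory_table(traj: OrientationTrajectory) -> pd.DataFrame:
    """Flat table ``t, qw, qx, qy, qz, lax, lay, laz`` for CSV export."""
    return pd.DataFrame(
        {
            "t": traj.t,
            "qw": traj.quats[:, 0],
            "qx": traj.quats[:, 1],
            "qy": traj.quats[:, 2],
            "qz": traj.quats[:, 3],
            "lax": traj.linacc[:, 0],
            "lay": traj.linacc[:, 1],
            "laz": traj.linacc[:, 2],
        }
    )


def align_motion_to_frames(
    traj: OrientationTrajectory, frame_times: Sequence[float]
) -> pd.DataFrame:
    """Nearest-sample orientation and linear acceleration per video frame.

    At 100 Hz IMU against 30 fps video the nearest sample is at most 5 ms
    away, so no interpolation is applied.  Frames outside the trajectory
    span are marked missing.
    """
    ft = np.asarray(frame_times, dtype=float)
    t = traj.t
    right = np.searchsorted(t, ft)
    left = np.clip(right - 1, 0, len(t) - 1)
    right = np.clip(right, 0, len(t) - 1)
    pick_right = np.abs(t[right] - ft) < np.abs(t[left] - ft)
    idx = np.where(pick_right, right, left)
    missing = (ft < t[0]) | (ft > t[-1])
    out = pd.DataFrame(
        {
            "t_frame": ft,
            "t_sample": t[idx],
            "qw": traj.quats[idx, 0],
            "qx": traj.quats[idx, 1],
            "qy": traj.quats[idx, 2],
            "qz": traj.quats[idx, 3],
            "lax": traj.linacc[idx, 0],
            "lay": traj.linacc[idx, 1],
            "laz": traj.linacc[idx, 2],
            "missing": missing,
        }
    )
    return out


def event_anchored_panel(
    traj: OrientationTrajectory,
    t_event: float,
    n_seconds: int = 5,
    tick: float = 1.0,
) -> pd.DataFrame:
    """Motion summary at 1-s ticks leading up to an event (freeze at t=0).

    Returns ``n_seconds + 1`` rows at offsets ``-n_seconds .. 0`` seconds
    relative to the event, each with the nearest-sample orientation and
    linear acceleration — the per-frame motion panel of an acquisition.
    """
    offsets = np.arange(-n_seconds, 1) * tick
    panel = align_motion_to_frames(traj, t_event + offsets)
    panel.insert(0, "offset_s", offsets)
    return panel
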