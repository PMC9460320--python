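"""Quaternion kinematics and gravity-referenced IMU orientation fusion.

Conventions
-----------
Quaternions are length-4 arrays ``(q0, q1, q2, q3)``, scalar part first,
encoding the **sensor-to-global** rotation: a vector ``v`` expressed in the
sensor frame maps to the global frame as ``q ⊗ (0, v) ⊗ q*``.  The columns of
the corresponding rotation matrix are therefore the sensor axes expressed in
the global frame.  The global frame is the pool frame used throughout the
package: X transverse (right positive), Y along the swimming direction
(forward positive), Z vertical (up positive), origin at the water surface.

The accelerometer measures specific force: a sensor at rest with its frame
aligned to the global frame reads ``(0, 0, +g)``.  Gyroscope rates are
rad·s⁻¹ in the sensor frame (file readers convert deg·s⁻¹ when configured).

Orientation from a 6-axis IMU is estimated with the magnetometer-free variant
of Madgwick's gradient-descent fusion filter: the quaternion rate from the
gyroscope, ``0.5·q ⊗ (0, ω)``, is corrected by descending the
gravity-alignment objective (predicted minus measured gravity direction in
the sensor frame) at rate ``β``, then integrated with a first-order step and
renormalized.  Heading (rotation about gravity) is unobservable without a
magnetometer, but the propulsive projection only needs the palm-normal
direction, which is gravity-referenced at the start pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRAVITY",
    "DEFAULT_BETA",
    "ImuSample",
    "ImuStream",
    "quat_normalize",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "quat_from_axis_angle",
    "quat_angle",
    "quat_to_rotmat",
    "z_axis_y_component",
    "tilt_from_accel",
    "madgwick_update",
    "fuse_stream",
]

#: standard gravity, m·s⁻²
GRAVITY = 9.80665

#: default divergence rate of the gradient-descent fusion filter
DEFAULT_BETA = 0.033

_UNIT_TOL = 1e-6
_IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class ImuSample:
    """One timestamped 6-axis IMU reading in the sensor frame."""

    t: float
    gyro: np.ndarray  # rad/s, shape (3,)
    accel: np.ndarray  # m/s^2, shape (3,)

    def __post_init__(self) -> None:
        gyro = np.asarray(self.gyro, dtype=float)
        accel = np.asarray(self.accel, dtype=float)
        if gyro.shape != (3,) or accel.shape != (3,):
            raise ValueError("gyro and accel must be 3-vectors")
        if not (np.isfinite(gyro).all() and np.isfinite(accel).all() and math.isfinite(self.t)):
            raise ValueError("non-finite IMU sample")
        object.__setattr__(self, "gyro", gyro)
        object.__setattr__(self, "accel", accel)


@dataclass
class ImuStream:
    """Uniformly sampled IMU recording (arrays of shape (N,) / (N, 3))."""

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        n = self.t.shape[0]
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError("gyro/accel must have shape (N, 3) matching t")
        if not (np.isfinite(self.t).all() and np.isfinite(self.gyro).all() and np.isfinite(self.accel).all()):
            raise ValueError("non-finite values in IMU stream")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise ValueError(f"timestamps not strictly increasing at sample {bad}")

    @classmethod
    def from_samples(cls, samples) -> "ImuStream":
        samples = list(samples)
        if not samples:
            return cls(np.empty(0), np.empty((0, 3)), np.empty((0, 3)))
        return cls(
            np.array([s.t for s in samples]),
            np.array([s.gyro for s in samples]),
            np.array([s.accel for s in samples]),
        )

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self):
        for i in range(len(self)):
            yield ImuSample(float(self.t[i]), self.gyro[i], self.accel[i])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Return q scaled to unit norm (raises on zero norm)."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("cannot normalize zero quaternion")
    return q / norm


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b (composition of the two rotations); broadcasts."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0, a1, a2, a3 = np.moveaxis(a, -1, 0)
    b0, b1, b2, b3 = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
            a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
            a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
            a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate sensor-frame vector(s) v into the global frame: q ⊗ (0,v) ⊗ q*."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    zeros = np.zeros(v.shape[:-1] + (1,))
    vq = np.concatenate([zeros, v], axis=-1)
    return quat_multiply(quat_multiply(q, vq), quat_conjugate(q))[..., 1:]


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("zero rotation axis")
    half = 0.5 * angle
    return np.concatenate([[math.cos(half)], math.sin(half) * axis / norm])


def quat_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Rotation angle (rad) between two unit quaternions, sign-ambiguity free."""
    dot = float(np.clip(abs(np.dot(np.asarray(a), np.asarray(b))), -1.0, 1.0))
    return 2.0 * math.acos(dot)


def quat_to_rotmat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix whose columns are the sensor axes in the global frame.

    Rejects inputs whose norm deviates from 1 beyond a small tolerance rather
    than silently renormalizing.
    """
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > _UNIT_TOL:
        raise ValueError("quaternion is not unit-norm")
    q0, q1, q2, q3 = q
    return np.array(
        [
            [q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3],
        ]
    )


def z_axis_y_component(q: np.ndarray) -> float | np.ndarray:
    """Y component of the sensor z-axis in the global frame, ``2(q2·q3 − q0·q1)``.

    This is the middle entry of the third column of :func:`quat_to_rotmat`;
    with the sensor z-axis orthogonal to the palm it is the factor projecting
    the resultant hand force onto the swimming direction.  Vectorized over a
    trailing-axis-4 array of quaternions.
    """
    q = np.asarray(q, dtype=float)
    return 2.0 * (q[..., 2] * q[..., 3] - q[..., 0] * q[..., 1])


def tilt_from_accel(accel: np.ndarray) -> np.ndarray:
    """Minimal-rotation quaternion aligning the measured gravity with global up.

    Uses only the accelerometer direction (valid when linear acceleration is
    small), leaving heading at its minimal-rotation value.
    """
    a = np.asarray(accel, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("zero accelerometer vector")
    a = a / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(a, z)
    s = np.linalg.norm(axis)
    c = float(np.clip(np.dot(a, z), -1.0, 1.0))
    if s < 1e-12:
        if c > 0:
            return _IDENTITY.copy()
        return np.array([0.0, 1.0, 0.0, 0.0])  # upside down: 180° about x
    return quat_from_axis_angle(axis, math.atan2(s, c))


def madgwick_update(
    q_prev: np.ndarray,
    sample: ImuSample,
    dt: float,
    beta: float = DEFAULT_BETA,
) -> np.ndarray:
    """Advance the orientation one step from a gyro+accel sample.

    The quaternion rate is the gyroscope term ``0.5·q ⊗ (0, ω)`` minus ``β``
    times the normalized gradient of the gravity-alignment objective
    (predicted gravity direction — the third row of the rotation matrix —
    minus the normalized accelerometer reading).  A zero accelerometer (or
    ``beta = 0``) degenerates to pure gyro integration.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gx, gy, gz = (float(x) for x in sample.gyro)
    ax, ay, az = (float(x) for x in sample.accel)
    if not all(map(math.isfinite, (gx, gy, gz, ax, ay, az))):
        raise ValueError("NaN/inf in IMU sample")
    q0, q1, q2, q3 = (float(x) for x in q_prev)
    return np.array(_step(q0, q1, q2, q3, gx, gy, gz, ax, ay, az, dt, beta))


def _step(q0, q1, q2, q3, gx, gy, gz, ax, ay, az, dt, beta):
    """Scalar-arithmetic fusion step (no validation); see madgwick_update."""
    q_dot0 = 0.5 * (-q1 * gx - q2 * gy - q3 * gz)
    q_dot1 = 0.5 * (q0 * gx + q2 * gz - q3 * gy)
    q_dot2 = 0.5 * (q0 * gy - q1 * gz + q3 * gx)
    q_dot3 = 0.5 * (q0 * gz + q1 * gy - q2 * gx)

    a_norm = math.sqrt(ax * ax + ay * ay + az * az)
    if a_norm > 0.0 and beta > 0.0:
        ax, ay, az = ax / a_norm, ay / a_norm, az / a_norm
        # objective: predicted gravity direction in the sensor frame vs accel
        f1 = 2.0 * (q1 * q3 - q0 * q2) - ax
        f2 = 2.0 * (q0 * q1 + q2 * q3) - ay
        f3 = 2.0 * (0.5 - q1 * q1 - q2 * q2) - az
        g0 = -2.0 * q2 * f1 + 2.0 * q1 * f2
        g1 = 2.0 * q3 * f1 + 2.0 * q0 * f2 - 4.0 * q1 * f3
        g2 = -2.0 * q0 * f1 + 2.0 * q3 * f2 - 4.0 * q2 * f3
        g3 = 2.0 * q1 * f1 + 2.0 * q2 * f2
        g_norm = math.sqrt(g0 * g0 + g1 * g1 + g2 * g2 + g3 * g3)
        if g_norm > 0.0:
            q_dot0 -= beta * g0 / g_norm
            q_dot1 -= beta * g1 / g_norm
            q_dot2 -= beta * g2 / g_norm
            q_dot3 -= beta * g3 / g_norm

    q0 += q_dot0 * dt
    q1 += q_dot1 * dt
    q2 += q_dot2 * dt
    q3 += q_dot3 * dt
    norm = math.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    return (q0 / norm, q1 / norm, q2 / norm, q3 / norm)


def fuse_stream(
    stream: ImuStream | list,
    q_init: np.ndarray | str | None = None,
    beta: float = DEFAULT_BETA,
    dt_tolerance: float = 0.5,
) -> np.ndarray:
    """Fold :func:`madgwick_update` over a uniformly sampled stream.

    Parameters
    ----------
    stream
        :class:`ImuStream` or sequence of :class:`ImuSample` at a nominally
        uniform rate.
    q_init
        Initial orientation.  ``None`` → identity (the start pose: palm down,
        sensor z up); ``"accel"`` → tilt from the first accelerometer sample;
        otherwise an explicit unit quaternion.
    beta
        Fusion divergence rate.
    dt_tolerance
        Relative deviation of any timestamp step from the median step that is
        treated as a gap and rejected.

    Returns
    -------
    (N, 4) array, one orientation per input sample; the first output is
    ``q_init`` advanced one step.
    """
    if not isinstance(stream, ImuStream):
        stream = ImuStream.from_samples(stream)
    n = len(stream)
    if n == 0:
        return np.empty((0, 4))

    if isinstance(q_init, str):
        if q_init != "accel":
            raise ValueError(f"unknown q_init mode {q_init!r}")
        q = tilt_from_accel(stream.accel[0])
    elif q_init is None:
        q = _IDENTITY.copy()
    else:
        q = quat_normalize(np.asarray(q_init, dtype=float))

    if n == 1:
        raise ValueError("cannot infer sample interval from a single sample")
    dts = np.diff(stream.t)
    med = float(np.median(dts))
    bad = np.flatnonzero(np.abs(dts - med) > dt_tolerance * med)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"timestamp gap at sample {i + 1} (t = {stream.t[i + 1]:.6f} s, dt = {dts[i]:.6f} s)"
        )

    out = np.empty((n, 4))
    q0, q1, q2, q3 = (float(x) for x in q)
    gyro = stream.gyro.tolist()
    accel = stream.accel.tolist()
    dt_list = dts.tolist()
    for i in range(n):
        dt = dt_list[i - 1] if i > 0 else dt_list[0]
        gx, gy, gz = gyro[i]
        ax, ay, az = accel[i]
        q0, q1, q2, q3 = _step(q0, q1, q2, q3, gx, gy, gz, ax, ay, az, dt, beta)
        out[i, 0] = q0
        out[i, 1] = q1
        out[i, 2] = q2
        out[i, 3] = q3
    return out
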