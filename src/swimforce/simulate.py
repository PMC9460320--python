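"""Synthetic underwater-stroke generator with exact ground truth.

Emulates the three synchronized 200 Hz recordings the estimation pipelines
consume — six-channel palm/dorsal pressures, five hand-landmark trajectories
and a 6-axis IMU stream — from a closed-form hand trajectory, so both
estimation pathways and the agreement statistics can be exercised against a
known propulsive-force truth without any real data.

The hand orientation is parameterized in closed form (a quintic-smoothstep
pitch sweep about the transverse axis composed with a windowed sinusoidal
roll about the finger axis), so the sensor-frame angular velocity is analytic
rather than numerically differentiated.  The fingertip height is an analytic
sinusoid crossing the water surface exactly at the nominal entry and exit
times, and the resultant force is a half-sine pulse over the underwater
phase.  Defaults describe a front-crawl-like stroke: 1.2 s underwater phase,
pitch sweeping −20° → −160° (fingers forward-down at entry, backward-up at
exit), 0.4 m fingertip depth, 20 N peak resultant force, 1.2 m·s⁻¹ forward
speed.

Sensor-noise defaults emulate the measurement chain: 0.01 rad·s⁻¹ gyro and
0.1 m·s⁻² accelerometer white noise, 2 mm marker noise (the order of the
motion-capture calibration residuals), 0.05 kPa pressure noise; gyro bias
and marker dropout are available but default to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import orientation as ori
from .pipeline import MARKER_LABELS, HandGeometry, MarkerStream, PressureStream

__all__ = [
    "StrokeParams",
    "NoiseSpec",
    "StrokeTruth",
    "SimulatedStroke",
    "default_geometry",
    "marker_layout",
    "simulate_stroke",
    "synthesize_imu",
    "synthesize_markers",
    "synthesize_pressure",
    "simulate_study",
]

_TIP_LENGTH = 0.18  # m, wrist-midpoint to third fingertip in the sensor frame


def default_geometry(side: str = "right") -> HandGeometry:
    """Equal-thirds segmentation of a 0.017 m² adult hand."""
    s = 0.017 / 3.0
    return HandGeometry(s, s, s, side=side)


@dataclass(frozen=True)
class StrokeParams:
    """Closed-form stroke description (angles in rad, SI units)."""

    phase_duration: float = 1.2  # s underwater
    lead_in: float = 0.4  # s above water before entry
    lead_out: float = 0.4  # s above water after exit
    fs: float = 200.0  # Hz
    pitch_entry: float = math.radians(-20.0)
    pitch_exit: float = math.radians(-160.0)
    roll_amplitude: float = math.radians(15.0)
    peak_force: float = 20.0  # N, resultant-force pulse peak
    tip_depth: float = 0.4  # m, fingertip depth scale
    swim_speed: float = 1.2  # m/s forward
    side: str = "right"

    def __post_init__(self) -> None:
        if self.phase_duration <= 0 or self.fs <= 0:
            raise ValueError("phase duration and sampling rate must be positive")
        if self.lead_in < 0 or self.lead_out < 0:
            raise ValueError("lead times must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive sensor-noise model; all randomness flows from ``seed``."""

    gyro_sd: float = 0.01  # rad/s
    gyro_bias: tuple = (0.0, 0.0, 0.0)  # rad/s
    accel_sd: float = 0.1  # m/s^2
    marker_sd: float = 0.002  # m
    marker_dropout: float = 0.0  # probability per marker per sample
    pressure_sd: float = 0.05  # kPa
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gyro_sd", "accel_sd", "marker_sd", "pressure_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.marker_dropout < 1:
            raise ValueError("marker_dropout must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class StrokeTruth:
    """Ground-truth trajectory: everything the sensors are synthesized from."""

    t: np.ndarray
    q: np.ndarray  # (N, 4) sensor-to-global
    omega: np.ndarray  # (N, 3) rad/s, sensor frame
    pos: np.ndarray  # (N, 3) hand origin, global frame, m
    a_lin: np.ndarray  # (N, 3) linear acceleration of hand origin, global, m/s^2
    fr: np.ndarray  # (N,) resultant force, N
    z_y: np.ndarray  # (N,) Y component of the palm-orthogonal axis
    f: np.ndarray  # (N,) propulsive force truth, N
    entry: float
    exit: float
    params: StrokeParams

    @property
    def fs(self) -> float:
        return self.params.fs

    def phase_mask(self) -> np.ndarray:
        return (self.t >= self.entry) & (self.t <= self.exit)

    def mean_force(self) -> float:
        return float(np.mean(self.f[self.phase_mask()]))


@dataclass
class SimulatedStroke:
    truth: StrokeTruth
    imu: ori.ImuStream
    markers: MarkerStream
    pressure: PressureStream
    geometry: HandGeometry


def _smootherstep(u: np.ndarray):
    """C² quintic smoothstep and its first/second derivatives on [0, 1]."""
    s = u**3 * (6.0 * u**2 - 15.0 * u + 10.0)
    ds = 30.0 * u**2 * (u - 1.0) ** 2
    d2s = 60.0 * u * (2.0 * u - 1.0) * (u - 1.0)
    return s, ds, d2s


def simulate_stroke(params: StrokeParams | None = None) -> StrokeTruth:
    """Generate the ground-truth trajectory of one stroke (deterministic).

    The window spans lead-in, underwater phase, and lead-out; the fingertip
    height crosses zero downward exactly at ``entry = lead_in`` and upward at
    ``exit = lead_in + phase_duration``, so phase detection on the noise-free
    fingertip trace recovers the nominal boundaries.
    """
    p = params or StrokeParams()
    n = int(round((p.lead_in + p.phase_duration + p.lead_out) * p.fs)) + 1
    t = np.arange(n) / p.fs
    entry = p.lead_in
    exit_ = p.lead_in + p.phase_duration
    tp = p.phase_duration

    u = np.clip((t - entry) / tp, 0.0, 1.0)
    inside = (t > entry) & (t < exit_)
    du = np.where(inside, 1.0 / tp, 0.0)

    s, ds, d2s = _smootherstep(u)
    dphi_total = p.pitch_exit - p.pitch_entry
    phi = p.pitch_entry + dphi_total * s
    phi_dot = dphi_total * ds * du
    phi_ddot = dphi_total * d2s * du**2

    # windowed roll: zero value/rate outside the phase, C² at the boundaries
    rho = p.roll_amplitude * np.sin(np.pi * u) ** 2 * np.sin(2.0 * np.pi * u)
    # d/du [sin²(πu)·sin(2πu)] = 2π·sin(πu)·cos(πu)·sin(2πu) + 2π·sin²(πu)·cos(2πu)
    drho_du = p.roll_amplitude * (
        2.0 * np.pi * np.sin(np.pi * u) * np.cos(np.pi * u) * np.sin(2.0 * np.pi * u)
        + 2.0 * np.pi * np.sin(np.pi * u) ** 2 * np.cos(2.0 * np.pi * u)
    )
    rho_dot = drho_du * du

    qx = np.stack([np.cos(phi / 2), np.sin(phi / 2), np.zeros(n), np.zeros(n)], axis=-1)
    qy = np.stack([np.cos(rho / 2), np.zeros(n), np.sin(rho / 2), np.zeros(n)], axis=-1)
    q = ori.quat_multiply(qx, qy)

    # body rates of the pitch∘roll chain: ω = Ry(ρ)ᵀ·(φ̇ x̂) + ρ̇ ŷ
    omega = np.stack([phi_dot * np.cos(rho), rho_dot, phi_dot * np.sin(rho)], axis=-1)

    # fingertip height: analytic sinusoid crossing 0 at entry (down) and exit (up)
    w_p = np.pi / tp
    zeta = -p.tip_depth * np.sin(w_p * (t - entry))
    z0 = zeta - _TIP_LENGTH * np.sin(phi)
    z0_ddot = p.tip_depth * w_p**2 * np.sin(w_p * (t - entry)) - _TIP_LENGTH * (
        np.cos(phi) * phi_ddot - np.sin(phi) * phi_dot**2
    )
    pos = np.stack([np.zeros(n), p.swim_speed * t, z0], axis=-1)
    a_lin = np.stack([np.zeros(n), np.zeros(n), z0_ddot], axis=-1)

    fr = np.where(inside | np.isclose(t, entry) | np.isclose(t, exit_), p.peak_force * np.sin(np.pi * u), 0.0)
    z_y = -np.sin(phi) * np.cos(rho)
    f = fr * z_y

    return StrokeTruth(t, q, omega, pos, a_lin, fr, z_y, f, entry, exit_, p)


def synthesize_imu(truth: StrokeTruth, noise: NoiseSpec, rng=None) -> ori.ImuStream:
    """IMU stream implied by the truth: body rates plus specific force.

    The accelerometer reads the specific force in the sensor frame,
    ``Rᵀ·(a_lin − g⃗)`` with ``g⃗ = (0, 0, −g)``; a static aligned sensor
    therefore reads ``(0, 0, +g)``.  A zero-noise spec reproduces the truth
    exactly, and a fixed seed reproduces the stream bit for bit.
    """
    rng = rng if rng is not None else noise.rng()
    n = len(truth.t)
    gravity_vec = np.array([0.0, 0.0, -ori.GRAVITY])
    specific = truth.a_lin - gravity_vec
    accel = ori.quat_rotate(ori.quat_conjugate(truth.q), specific)
    gyro = truth.omega + np.asarray(noise.gyro_bias, dtype=float)
    if noise.gyro_sd > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_sd, (n, 3))
    if noise.accel_sd > 0:
        accel = accel + rng.normal(0.0, noise.accel_sd, (n, 3))
    return ori.ImuStream(truth.t.copy(), gyro, accel)


def marker_layout(side: str = "right", hand_area: float = 0.017) -> dict:
    """Sensor-frame landmark coordinates (m), scaled to the hand area.

    The wrist-styloid midpoint sits at the origin and the third fingertip
    lies on +y, matching the mounting rule that the sensor y-axis runs from
    the styloid midpoint to the fingertip.  On the right hand the 2nd
    metacarpophalangeal joint is radial (−x); the left hand is the x-mirror.
    """
    scale = math.sqrt(hand_area / 0.017)
    layout = {
        "second_mcp": np.array([-0.035, 0.095, 0.0]),
        "fifth_mcp": np.array([0.035, 0.085, 0.0]),
        "rst": np.array([-0.03, 0.0, 0.0]),
        "ust": np.array([0.03, 0.0, 0.0]),
        "third_tip": np.array([0.0, _TIP_LENGTH, 0.0]),
    }
    if side == "left":
        layout = {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in layout.items()}
    elif side != "right":
        raise ValueError("side must be 'left' or 'right'")
    return {k: v * scale for k, v in layout.items()}


def synthesize_markers(
    truth: StrokeTruth,
    geom: HandGeometry,
    noise: NoiseSpec,
    rng=None,
) -> MarkerStream:
    """Five-landmark trajectories implied by the truth pose."""
    rng = rng if rng is not None else noise.rng()
    layout = marker_layout(geom.side, geom.total_area)
    n = len(truth.t)
    pos = {}
    valid = {}
    for label in MARKER_LABELS:
        world = ori.quat_rotate(truth.q, np.broadcast_to(layout[label], (n, 3))) + truth.pos
        if noise.marker_sd > 0:
            world = world + rng.normal(0.0, noise.marker_sd, (n, 3))
        ok = np.ones(n, dtype=bool)
        if noise.marker_dropout > 0:
            ok = rng.random(n) >= noise.marker_dropout
            world = world.copy()
            world[~ok] = np.nan
        pos[label] = world
        valid[label] = ok
    return MarkerStream(truth.t.copy(), pos, valid)


def synthesize_pressure(
    truth: StrokeTruth,
    geom: HandGeometry,
    noise: NoiseSpec,
    rng=None,
    weights=(1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
) -> PressureStream:
    """Six-channel pressures inverting the resultant-force equation.

    Segment i carries the palm−dorsal difference ``wᵢ·FR/Sᵢ`` (Pa, reported
    in kPa) split symmetrically about a common hydrostatic baseline, so the
    resultant-force computation on the noise-free output returns the truth
    exactly.
    """
    rng = rng if rng is not None else noise.rng()
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("weights must be 3 non-negative values summing to 1")
    areas = geom.areas
    if np.any(areas <= 0):
        raise ValueError("zero or negative segment area")
    n = len(truth.t)
    diff_kpa = truth.fr[:, None] * w[None, :] / areas[None, :] / 1000.0
    depth = np.maximum(0.0, -truth.pos[:, 2])
    baseline = 997.0 * ori.GRAVITY * depth[:, None] / 1000.0  # kPa, hydrostatic
    p = baseline + 0.5 * diff_kpa
    d = baseline - 0.5 * diff_kpa
    if noise.pressure_sd > 0:
        p = p + rng.normal(0.0, noise.pressure_sd, (n, 3))
        d = d + rng.normal(0.0, noise.pressure_sd, (n, 3))
    return PressureStream(truth.t.copy(), p, d)


def _draw_params(base: StrokeParams, rng: np.random.Generator) -> StrokeParams:
    """Per-stroke variation: peak force, duration and exit pitch vary between
    strokes the way successive strokes of a swimmer differ."""
    return replace(
        base,
        peak_force=float(rng.uniform(10.0, 30.0)),
        phase_duration=float(rng.uniform(1.0, 1.4)),
        pitch_exit=base.pitch_exit + math.radians(float(rng.uniform(-10.0, 10.0))),
        roll_amplitude=float(rng.uniform(math.radians(5.0), math.radians(20.0))),
    )


def simulate_study(
    n_strokes: int,
    seed: int,
    noise: NoiseSpec | None = None,
    base_params: StrokeParams | None = None,
    geometry: HandGeometry | None = None,
    vary: bool = True,
) -> list:
    """Simulate a set of strokes with per-stroke parameter variation.

    Returns a list of :class:`SimulatedStroke`; all randomness (parameter
    draws and every sensor noise stream) descends from ``seed``.
    """
    if n_strokes < 1:
        raise ValueError("need at least one stroke")
    noise = noise if noise is not None else NoiseSpec()
    base = base_params if base_params is not None else StrokeParams()
    geom = geometry if geometry is not None else default_geometry(base.side)
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(n_strokes)
    out = []
    for child in children:
        params = _draw_params(base, param_rng) if vary else base
        truth = simulate_stroke(params)
        rngs = [np.random.default_rng(s) for s in child.spawn(3)]
        imu = synthesize_imu(truth, noise, rngs[0])
        markers = synthesize_markers(truth, geom, noise, rngs[1])
        pressure = synthesize_pressure(truth, geom, noise, rngs[2])
        out.append(SimulatedStroke(truth, imu, markers, pressure, geom))
    return out
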