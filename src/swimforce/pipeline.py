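"""Hand propulsive-force estimation from paired palm/dorsal pressure sensors
plus either marker-based or IMU-based hand orientation.

The resultant hydrodynamic force on the hand is

    FR = Σᵢ Sᵢ·(pᵢ − dᵢ),   i = 1..3,

the palm-minus-dorsal pressure difference of each sensor pair integrated over
its hand-plane segment area Sᵢ.  FR acts along the palm normal (positive
toward the dorsum when palm pressure exceeds dorsal pressure).  Projecting it
onto the swimming direction (global +Y) gives the propulsive force

    F = FR·z_y,

where z is the unit palm-orthogonal direction pointing out the dorsal side,
obtained either from five hand landmarks (motion capture) or from the
sensor-frame z-axis of a hand-mounted IMU, z_y = 2(q2·q3 − q0·q1).

Marker-based normal: V1 runs from the midpoint of the ulnar and radial
styloid markers to the third fingertip; V2 runs from the 2nd to the 5th
metacarpophalangeal joint on the right hand (reversed on the left, which
makes the normal palm-relative on both sides); z = (V2 × V1)/‖V2 × V1‖.

Per-stroke analysis windows run from water entry to water exit of the third
fingertip, detected as downward/upward zero crossings of its vertical
coordinate (water surface at Z = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import orientation as ori
from . import signalproc as sp

__all__ = [
    "MARKER_LABELS",
    "HandGeometry",
    "PressureStream",
    "MarkerStream",
    "StrokeRecord",
    "EstimationResult",
    "resultant_force",
    "mocap_hand_normal",
    "propulsive_force_mocap",
    "propulsive_force_imu",
    "stroke_phase",
    "stroke_mean_force",
    "extract_strokes",
    "fill_short_marker_gaps",
    "estimate_mocap",
    "estimate_imu",
]

#: required hand landmarks: 2nd/5th metacarpophalangeal joints, radial and
#: ulnar styloids, third fingertip
MARKER_LABELS = ("second_mcp", "fifth_mcp", "rst", "ust", "third_tip")

_KPA_TO_PA = 1000.0


@dataclass(frozen=True)
class HandGeometry:
    """Segmented hand-plane areas (m²) for the three sensor pairs.

    The hand plane is split into three segments by the ulnar styloid, radial
    styloid and their midpoint; sensor pair i sits on segment i.  Total area
    is sanity-checked against the plausible human range (adult hands measure
    roughly 0.014–0.02 m²).
    """

    S1: float
    S2: float
    S3: float
    side: str = "right"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        for name in ("S1", "S2", "S3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"segment area {name} must be positive")
        if not 0.005 <= self.total_area <= 0.05:
            raise ValueError(
                f"total hand area {self.total_area:.4f} m² outside the plausible band [0.005, 0.05]"
            )

    @property
    def total_area(self) -> float:
        return self.S1 + self.S2 + self.S3

    @property
    def areas(self) -> np.ndarray:
        return np.array([self.S1, self.S2, self.S3])


@dataclass
class PressureStream:
    """Paired palm (p) / dorsal (d) pressures in kPa, shape (N, 3) each."""

    t: np.ndarray
    p: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        n = self.t.shape[0]
        if self.p.shape != (n, 3) or self.d.shape != (n, 3):
            raise ValueError("palm/dorsal pressures must have shape (N, 3)")
        if not (np.isfinite(self.p).all() and np.isfinite(self.d).all()):
            raise ValueError("non-finite pressure values")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class MarkerStream:
    """Global-frame positions (m) of the five hand landmarks.

    ``pos[label]`` has shape (N, 3); ``valid[label]`` flags frames where the
    marker was tracked.  Invalid frames carry NaN coordinates and are never
    silently interpolated by the reader.
    """

    t: np.ndarray
    pos: dict
    valid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.shape[0]
        missing = [m for m in MARKER_LABELS if m not in self.pos]
        if missing:
            raise ValueError(f"missing required markers: {missing}; required: {list(MARKER_LABELS)}")
        for label in MARKER_LABELS:
            arr = np.asarray(self.pos[label], dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"marker {label} must have shape (N, 3)")
            self.pos[label] = arr
            if label not in self.valid:
                self.valid[label] = np.isfinite(arr).all(axis=1)
            else:
                self.valid[label] = np.asarray(self.valid[label], dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    def all_valid(self) -> np.ndarray:
        ok = np.ones(len(self), dtype=bool)
        for label in MARKER_LABELS:
            ok &= self.valid[label]
        return ok


@dataclass
class StrokeRecord:
    """Per-stroke paired force waveform over one underwater phase."""

    method: str  # "mocap" | "imu" | "truth"
    entry: float
    exit: float
    t: np.ndarray
    fr: np.ndarray
    z_y: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        if not self.entry < self.exit:
            raise ValueError("stroke entry time must precede exit time")
        if len(self.t) == 0:
            raise ValueError("stroke phase contains no samples")
        if np.any(np.abs(self.z_y) > 1 + 1e-9):
            raise ValueError("|z_y| exceeds 1")

    @property
    def mean_force(self) -> float:
        return float(np.mean(self.f))

    @property
    def duration(self) -> float:
        return self.exit - self.entry


@dataclass
class EstimationResult:
    """Full-trial output of one estimation pathway."""

    method: str
    t: np.ndarray
    fr: np.ndarray
    z_y: np.ndarray
    f: np.ndarray
    phases: list
    strokes: list


def resultant_force(pressure: PressureStream, geom: HandGeometry) -> np.ndarray:
    """Resultant force FR (N) from palm−dorsal pressure differences (kPa)."""
    diff_pa = (pressure.p - pressure.d) * _KPA_TO_PA
    return diff_pa @ geom.areas


def mocap_hand_normal(markers: MarkerStream, side: str) -> np.ndarray:
    """Unit palm-orthogonal direction (dorsal-pointing) from the marker set.

    Returns an (N, 3) array; frames with any invalid marker yield NaN rows.
    Raises if the finger and knuckle vectors are collinear anywhere (the
    cross product would be undefined).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    mid = 0.5 * (markers.pos["ust"] + markers.pos["rst"])
    v1 = markers.pos["third_tip"] - mid
    if side == "right":
        v2 = markers.pos["fifth_mcp"] - markers.pos["second_mcp"]
    else:
        v2 = markers.pos["second_mcp"] - markers.pos["fifth_mcp"]
    normal = np.cross(v2, v1)
    norm = np.linalg.norm(normal, axis=1)
    ok = markers.all_valid()
    scale = np.nanmax(np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)) if len(markers) else 1.0
    if np.any(norm[ok] < 1e-9 * max(scale, 1e-12)):
        bad = int(np.flatnonzero(ok & (norm < 1e-9 * max(scale, 1e-12)))[0])
        raise ValueError(f"collinear finger/knuckle vectors at frame {bad}")
    out = np.full_like(normal, np.nan)
    out[ok] = normal[ok] / norm[ok, None]
    return out


def propulsive_force_mocap(fr: np.ndarray, z_mocap: np.ndarray) -> np.ndarray:
    """Propulsive force F = FR·z_y with the marker-derived palm normal."""
    fr = np.asarray(fr, dtype=float)
    z_mocap = np.asarray(z_mocap, dtype=float)
    if len(fr) != len(z_mocap):
        raise ValueError("FR and orientation series must have equal length")
    return fr * z_mocap[:, 1]


def propulsive_force_imu(fr: np.ndarray, quats: np.ndarray) -> np.ndarray:
    """Propulsive force F = FR·2(q2·q3 − q0·q1) with the fused orientation."""
    fr = np.asarray(fr, dtype=float)
    quats = np.asarray(quats, dtype=float)
    if len(fr) != len(quats):
        raise ValueError("FR and quaternion series must have equal length")
    return fr * ori.z_axis_y_component(quats)


def stroke_phase(t: np.ndarray, z: np.ndarray, min_duration: float = 0.2) -> list:
    """Underwater phases (entry, exit) of a fingertip height trace.

    A phase opens at a downward zero crossing of ``z`` (entry into the water,
    surface at Z = 0) and closes at the next upward crossing (exit); crossing
    times are linearly interpolated.  Phases separated by a gap shorter than
    ``min_duration`` are merged, then phases shorter than ``min_duration``
    are discarded, which collapses noise-induced chatter around the surface
    into single events.  A hand that never exits yields no phase.
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(t) != len(z):
        raise ValueError("t and z must have equal length")
    if len(t) < 2:
        return []

    crossings = []  # (time, kind) with kind "entry" | "exit"
    for i in range(1, len(z)):
        z0, z1 = z[i - 1], z[i]
        if z0 >= 0 > z1:
            frac = z0 / (z0 - z1)
            crossings.append((t[i - 1] + frac * (t[i] - t[i - 1]), "entry"))
        elif z0 < 0 <= z1:
            frac = z0 / (z0 - z1)
            crossings.append((t[i - 1] + frac * (t[i] - t[i - 1]), "exit"))

    phases = []
    entry = None
    for time, kind in crossings:
        if kind == "entry" and entry is None:
            entry = time
        elif kind == "exit" and entry is not None:
            phases.append((entry, time))
            entry = None

    # merge phases separated by short above-water gaps (crossing chatter)
    merged = []
    for ph in phases:
        if merged and ph[0] - merged[-1][1] < min_duration:
            merged[-1] = (merged[-1][0], ph[1])
        else:
            merged.append(ph)
    return [ph for ph in merged if ph[1] - ph[0] >= min_duration]


def stroke_mean_force(record: StrokeRecord) -> float:
    """Arithmetic mean of the propulsive force over the underwater phase."""
    return record.mean_force


def extract_strokes(t, fr, z_y, f, phases, method: str) -> list:
    """Cut per-sample series into per-stroke records over the given phases."""
    t = np.asarray(t, dtype=float)
    records = []
    for entry, exit_ in phases:
        mask = (t >= entry) & (t <= exit_)
        if not mask.any():
            raise ValueError(f"phase ({entry:.3f}, {exit_:.3f}) s contains no samples")
        records.append(
            StrokeRecord(
                method=method,
                entry=float(entry),
                exit=float(exit_),
                t=t[mask],
                fr=np.asarray(fr, dtype=float)[mask],
                z_y=np.asarray(z_y, dtype=float)[mask],
                f=np.asarray(f, dtype=float)[mask],
            )
        )
    return records


def fill_short_marker_gaps(markers: MarkerStream, max_gap: int = 5) -> MarkerStream:
    """Linearly fill marker dropouts of at most ``max_gap`` samples.

    Longer gaps are left NaN/invalid; interpolating them would fabricate
    motion through an occlusion.
    """
    t = markers.t
    pos = {}
    valid = {}
    for label in MARKER_LABELS:
        arr = markers.pos[label].copy()
        ok = markers.valid[label].copy()
        bad = ~ok
        if bad.any() and ok.sum() >= 2:
            # locate runs of consecutive invalid samples
            idx = np.flatnonzero(bad)
            runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for run in runs:
                if len(run) <= max_gap and run[0] > 0 and run[-1] < len(t) - 1:
                    lo, hi = run[0] - 1, run[-1] + 1
                    if ok[lo] and ok[hi]:
                        for axis in range(3):
                            arr[run, axis] = np.interp(t[run], [t[lo], t[hi]], [arr[lo, axis], arr[hi, axis]])
                        ok[run] = True
        pos[label] = arr
        valid[label] = ok
    return MarkerStream(t, pos, valid)


def _filter_pressure(pressure: PressureStream, fc, fs) -> PressureStream:
    if fc is None:
        return pressure
    return PressureStream(
        pressure.t,
        sp.lowpass_filter(pressure.p, fc, fs),
        sp.lowpass_filter(pressure.d, fc, fs),
    )


def _filter_markers(markers: MarkerStream, fc, fs) -> MarkerStream:
    if fc is None:
        return markers
    pos = {label: sp.lowpass_filter(markers.pos[label], fc, fs) for label in MARKER_LABELS}
    return MarkerStream(markers.t, pos, dict(markers.valid))


def _check_aligned(t_a: np.ndarray, t_b: np.ndarray, what: str) -> None:
    if len(t_a) != len(t_b) or (len(t_a) and np.max(np.abs(t_a - t_b)) > 1e-6):
        raise ValueError(f"{what} streams are not sample-aligned; synchronize them first")


def estimate_mocap(
    pressure: PressureStream,
    markers: MarkerStream,
    geom: HandGeometry,
    cutoff_pressure: float | None = 20.0,
    cutoff_coords: float | None = 6.0,
    min_phase_duration: float = 0.2,
    max_marker_gap: int = 5,
) -> EstimationResult:
    """Motion-capture pathway: pressures + five hand landmarks → F(t), strokes.

    Pressures are smoothed at 20 Hz and coordinates at 6 Hz (residual-analysis
    defaults; pass ``None`` to skip a filter).  Underwater phases come from
    the third-fingertip height.
    """
    _check_aligned(pressure.t, markers.t, "pressure/marker")
    fs = 1.0 / float(np.median(np.diff(pressure.t)))
    markers = fill_short_marker_gaps(markers, max_marker_gap)
    markers_f = _filter_markers(markers, cutoff_coords, fs)
    pressure_f = _filter_pressure(pressure, cutoff_pressure, fs)

    fr = resultant_force(pressure_f, geom)
    z = mocap_hand_normal(markers_f, geom.side)
    f = propulsive_force_mocap(fr, z)
    phases = stroke_phase(markers_f.t, markers_f.pos["third_tip"][:, 2], min_phase_duration)
    strokes = extract_strokes(pressure.t, fr, z[:, 1], f, phases, "mocap")
    return EstimationResult("mocap", pressure.t, fr, z[:, 1], f, phases, strokes)


def estimate_imu(
    pressure: PressureStream,
    imu: ori.ImuStream,
    geom: HandGeometry,
    beta: float = ori.DEFAULT_BETA,
    q_init="accel",
    cutoff_pressure: float | None = 20.0,
    phases: list | None = None,
) -> EstimationResult:
    """IMU pathway: pressures + fused 6-axis orientation → F(t), strokes.

    The IMU alone cannot place the hand relative to the water surface, so
    underwater phases must be supplied (from the motion-capture pathway, a
    simulation truth, or manual annotation); with ``phases=None`` the result
    carries the continuous force series and no per-stroke records.
    """
    _check_aligned(pressure.t, imu.t, "pressure/IMU")
    fs = 1.0 / float(np.median(np.diff(pressure.t)))
    pressure_f = _filter_pressure(pressure, cutoff_pressure, fs)

    fr = resultant_force(pressure_f, geom)
    quats = ori.fuse_stream(imu, q_init=q_init, beta=beta)
    z_y = ori.z_axis_y_component(quats)
    f = propulsive_force_imu(fr, quats)
    phases = list(phases) if phases is not None else []
    strokes = extract_strokes(pressure.t, fr, z_y, f, phases, "imu") if phases else []
    return EstimationResult("imu", pressure.t, fr, z_y, f, phases, strokes)
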