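"""Readers/writers for the delimited-text stream dialects, and run configuration.

Dialects are fixed: comma-separated for sensor streams (IMU, pressure),
tab-separated for motion-capture exports; UTF-8, '.' decimal separator.
Readers validate and reject malformed input (missing columns, non-monotone
time, NaN in sensor channels) with the offending line number rather than
silently coercing; missing marker coordinates are flagged invalid, never
interpolated at read time.

Column layouts
--------------
IMU CSV:       t, gx, gy, gz, ax, ay, az          (s, rad/s or deg/s, m/s²)
pressure CSV:  t, p1, p2, p3, d1, d2, d3          (s, kPa)
mocap TSV:     frame, time, <marker>_x/_y/_z for the five landmarks
               (mm by default, configurable)
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .orientation import DEFAULT_BETA, ImuStream
from .pipeline import MARKER_LABELS, HandGeometry, MarkerStream, PressureStream, StrokeRecord
from .stats import AgreementReport

logger = logging.getLogger("swimforce")

__all__ = [
    "RunConfig",
    "read_imu_csv",
    "write_imu_csv",
    "read_pressure_csv",
    "write_pressure_csv",
    "read_mocap_tsv",
    "write_mocap_tsv",
    "read_geometry",
    "write_geometry",
    "write_forces_csv",
    "write_stroke_table",
    "read_stroke_table",
    "write_truth_csv",
    "write_report",
]

_IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]
_PRESSURE_COLUMNS = ["t", "p1", "p2", "p3", "d1", "d2", "d3"]


@dataclass
class RunConfig:
    """Processing defaults; values match the published analysis settings."""

    cutoff_coords: float = 6.0  # Hz, marker-coordinate low-pass cutoff
    cutoff_pressure: float = 20.0  # Hz, pressure low-pass cutoff
    beta: float = DEFAULT_BETA  # fusion divergence rate
    sample_rate: float = 200.0  # Hz
    gyro_units: str = "rad/s"  # or "deg/s"
    mocap_units: str = "mm"  # or "m"
    alpha: float = 0.05
    cmc_points: int = 101
    min_phase_duration: float = 0.2  # s
    seed: int = 0
    geometry_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        """Return a copy with non-None overrides applied (and logged)."""
        updates = {k: v for k, v in overrides.items() if v is not None}
        for k, v in updates.items():
            if getattr(self, k) != v:
                logger.info("config override: %s = %r", k, v)
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _check_finite(df: pd.DataFrame, columns, path) -> None:
    block = df[columns].to_numpy(dtype=float)
    bad = ~np.isfinite(block)
    if bad.any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        raise ValueError(f"{path}: non-finite value at line {row + 2}")  # +2: header + 1-based


def _check_monotone_time(t: np.ndarray, path) -> None:
    if len(t) > 1:
        d = np.diff(t)
        if np.any(d <= 0):
            row = int(np.flatnonzero(d <= 0)[0]) + 1
            raise ValueError(f"{path}: time not strictly increasing at line {row + 2}")


def read_imu_csv(path, gyro_units: str = "rad/s") -> ImuStream:
    """Read a 6-axis IMU recording; gyro converted to rad/s if logged in deg/s."""
    df = pd.read_csv(path)
    _require_columns(df, _IMU_COLUMNS, path)
    _check_finite(df, _IMU_COLUMNS, path)
    t = df["t"].to_numpy(dtype=float)
    _check_monotone_time(t, path)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if gyro_units == "deg/s":
        gyro = np.radians(gyro)
    elif gyro_units != "rad/s":
        raise ValueError("gyro_units must be 'rad/s' or 'deg/s'")
    return ImuStream(t, gyro, accel)


def write_imu_csv(stream: ImuStream, path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.gyro, stream.accel]), columns=_IMU_COLUMNS
    )
    df.to_csv(path, index=False)


def read_pressure_csv(path) -> PressureStream:
    """Read six-channel palm/dorsal pressures (kPa)."""
    df = pd.read_csv(path)
    _require_columns(df, _PRESSURE_COLUMNS, path)
    _check_finite(df, _PRESSURE_COLUMNS, path)
    t = df["t"].to_numpy(dtype=float)
    _check_monotone_time(t, path)
    return PressureStream(
        t,
        df[["p1", "p2", "p3"]].to_numpy(dtype=float),
        df[["d1", "d2", "d3"]].to_numpy(dtype=float),
    )


def write_pressure_csv(stream: PressureStream, path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.p, stream.d]), columns=_PRESSURE_COLUMNS
    )
    df.to_csv(path, index=False)


def _mocap_columns():
    cols = ["frame", "time"]
    for label in MARKER_LABELS:
        cols += [f"{label}_x", f"{label}_y", f"{label}_z"]
    return cols


def read_mocap_tsv(path, units: str = "mm") -> MarkerStream:
    """Read five-landmark trajectories from a tab-separated export.

    Blank cells mark occluded markers: the frame is flagged invalid for that
    marker (NaN coordinates), not interpolated.  Extra columns are ignored
    with a logged warning.
    """
    if units not in ("mm", "m"):
        raise ValueError("mocap units must be 'mm' or 'm'")
    df = pd.read_csv(path, sep="\t")
    required = _mocap_columns()
    _require_columns(df, required, path)
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, extra)
    t = df["time"].to_numpy(dtype=float)
    if not np.isfinite(t).all():
        row = int(np.flatnonzero(~np.isfinite(t))[0])
        raise ValueError(f"{path}: non-finite time at line {row + 2}")
    _check_monotone_time(t, path)
    scale = 1e-3 if units == "mm" else 1.0
    pos = {}
    for label in MARKER_LABELS:
        pos[label] = df[[f"{label}_x", f"{label}_y", f"{label}_z"]].to_numpy(dtype=float) * scale
    return MarkerStream(t, pos)


def write_mocap_tsv(stream: MarkerStream, path, units: str = "mm") -> None:
    if units not in ("mm", "m"):
        raise ValueError("mocap units must be 'mm' or 'm'")
    scale = 1e3 if units == "mm" else 1.0
    data = {"frame": np.arange(len(stream)), "time": stream.t}
    for label in MARKER_LABELS:
        arr = stream.pos[label] * scale
        arr = np.where(stream.valid[label][:, None], arr, np.nan)
        for i, ax in enumerate("xyz"):
            data[f"{label}_{ax}"] = arr[:, i]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_geometry(path) -> HandGeometry:
    """Hand geometry from YAML: keys S1, S2, S3 (m²) and side."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        return HandGeometry(
            S1=float(data["S1"]), S2=float(data["S2"]), S3=float(data["S3"]), side=data.get("side", "right")
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing geometry key {exc}") from exc


def write_geometry(geom: HandGeometry, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"S1": geom.S1, "S2": geom.S2, "S3": geom.S3, "side": geom.side}, fh)


def write_forces_csv(result, path) -> None:
    """Per-sample output of one estimation pathway: t, FR, z_y, F."""
    pd.DataFrame({"t": result.t, "fr": result.fr, "z_y": result.z_y, "f": result.f}).to_csv(
        path, index=False
    )


def write_stroke_table(records, path, waveform_dir=None, prefix: str = "stroke") -> None:
    """Per-stroke table: stroke id, phase boundaries, mean force, waveform ref.

    When ``waveform_dir`` is given, each stroke's force waveform is written to
    ``<prefix>_<id>.csv`` there and referenced from the table.
    """
    records = list(records)
    if not records:
        raise ValueError("no strokes to write")
    rows = []
    for i, rec in enumerate(records):
        ref = ""
        if waveform_dir is not None:
            waveform_dir = Path(waveform_dir)
            waveform_dir.mkdir(parents=True, exist_ok=True)
            ref = f"{prefix}_{i:03d}.csv"
            pd.DataFrame({"t": rec.t, "f": rec.f}).to_csv(waveform_dir / ref, index=False)
        rows.append(
            {
                "stroke": i,
                "method": rec.method,
                "entry": rec.entry,
                "exit": rec.exit,
                "mean_force": rec.mean_force,
                "waveform_file": ref,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stroke_table(path):
    """Read a per-stroke table; returns (DataFrame, list of waveform arrays).

    Waveform files are resolved relative to the table's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("stroke", "mean_force"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    waveforms = []
    for ref in df.get("waveform_file", pd.Series([""] * len(df))):
        if isinstance(ref, str) and ref:
            wf = pd.read_csv(path.parent / ref)
            waveforms.append(wf["f"].to_numpy(dtype=float))
        else:
            waveforms.append(None)
    return df, waveforms


def write_truth_csv(truth, path) -> None:
    """Ground-truth trajectory of a simulated stroke, for scoring."""
    cols = {
        "t": truth.t,
        "q0": truth.q[:, 0],
        "q1": truth.q[:, 1],
        "q2": truth.q[:, 2],
        "q3": truth.q[:, 3],
        "wx": truth.omega[:, 0],
        "wy": truth.omega[:, 1],
        "wz": truth.omega[:, 2],
        "x": truth.pos[:, 0],
        "y": truth.pos[:, 1],
        "z": truth.pos[:, 2],
        "fr": truth.fr,
        "z_y": truth.z_y,
        "f": truth.f,
    }
    df = pd.DataFrame(cols)
    df.attrs["entry"] = truth.entry
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# entry={truth.entry:.6f} exit={truth.exit:.6f}\n")
        df.to_csv(fh, index=False)


def write_report(report: AgreementReport, out_dir, config: RunConfig | None = None) -> None:
    """Write the agreement report: machine-readable CSV + human summary.

    Both carry the applied configuration snapshot for reproducibility.
    Raises rather than writing an empty report for an empty stroke set.
    """
    if report.n_strokes == 0:
        raise ValueError("refusing to write a report for zero strokes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = (config or RunConfig()).to_dict()

    ba = report.bland_altman
    icc = report.icc
    rows = {
        "n_strokes": report.n_strokes,
        "mean_x": report.mean_x,
        "sd_x": report.sd_x,
        "mean_y": report.mean_y,
        "sd_y": report.sd_y,
        "icc_2_1": icc.icc,
        "icc_ci_low": icc.ci_low,
        "icc_ci_high": icc.ci_high,
        "icc_p": icc.p,
        "icc_label": icc.label,
        "bias": ba.bias,
        "sd_diff": ba.sd_diff,
        "loa_low": ba.loa_low,
        "loa_high": ba.loa_high,
        "loa_ci_lower_limit": ba.ci_lower_limit,
        "loa_ci_upper_limit": ba.ci_upper_limit,
        "fixed_bias_t": ba.fixed_bias_t,
        "fixed_bias_p": ba.fixed_bias_p,
        "effect_size": ba.effect_size,
        "effect_size_label": ba.effect_size_label,
        "proportional_r": ba.proportional_r,
        "proportional_p": ba.proportional_p,
        "cmc_mean": report.cmc_mean,
        "cmc_label": report.cmc_label,
    }
    table = pd.DataFrame([rows])
    table.to_csv(out_dir / "report.csv", index=False)
    pd.DataFrame({"stroke": range(len(report.cmc_per_stroke)), "cmc": report.cmc_per_stroke}).to_csv(
        out_dir / "cmc_per_stroke.csv", index=False
    )
    with open(out_dir / "config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2)

    lines = [
        "Agreement report",
        "================",
        f"strokes compared: {report.n_strokes}",
        f"method X mean force: {report.mean_x:.3f} ± {report.sd_x:.3f} N",
        f"method Y mean force: {report.mean_y:.3f} ± {report.sd_y:.3f} N",
        "",
        f"ICC(2,1) = {icc.icc:.4f} (95% CI {icc.ci_low:.4f}–{icc.ci_high:.4f}, p = {icc.p:.3g}) — {icc.label} agreement",
        "",
        "Bland–Altman",
        f"  bias (X − Y): {ba.bias:.4f} N, SD of differences: {ba.sd_diff:.4f} N",
        f"  95% limits of agreement: {ba.loa_low:.4f} to {ba.loa_high:.4f} N",
        f"  LOA confidence bounds: lower {ba.ci_lower_limit:.4f}, upper {ba.ci_upper_limit:.4f} N",
        f"  fixed bias: t = {ba.fixed_bias_t:.3f}, p = {ba.fixed_bias_p:.3g} "
        f"({'detected' if ba.has_fixed_bias else 'not detected'}); effect size d = {ba.effect_size:.3f} ({ba.effect_size_label})",
        f"  proportional bias: r = {ba.proportional_r:.3f}, p = {ba.proportional_p:.3g} "
        f"({'detected' if ba.has_proportional_bias else 'not detected'})",
        "",
        f"waveform similarity: mean CMC = {report.cmc_mean:.4f} over {report.n_strokes} strokes "
        f"({report.cmc_label}), time-normalized to {report.n_points} points",
        "",
        "config snapshot: " + json.dumps(cfg),
    ]
    with open(out_dir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
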