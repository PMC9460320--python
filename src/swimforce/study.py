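"""End-to-end workflows: run both estimation pathways on simulated strokes
and score their agreement, either against each other (the field comparison:
motion capture vs IMU) or against the simulator truth (recovery scoring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import orientation as ori
from . import pipeline as pl
from . import simulate as sim
from . import stats as st

__all__ = [
    "estimate_both",
    "compare_pathways",
    "imu_truth_agreement",
]


def estimate_both(
    stroke: sim.SimulatedStroke,
    beta: float = ori.DEFAULT_BETA,
    cutoff_pressure: float | None = 20.0,
    cutoff_coords: float | None = 6.0,
    min_phase_duration: float = 0.2,
):
    """Run the mocap and IMU pathways on one simulated stroke.

    Underwater phases are detected from the (filtered) fingertip height of
    the marker stream and shared with the IMU pathway, mirroring how the two
    recordings are analyzed side by side.
    """
    res_mocap = pl.estimate_mocap(
        stroke.pressure,
        stroke.markers,
        stroke.geometry,
        cutoff_pressure=cutoff_pressure,
        cutoff_coords=cutoff_coords,
        min_phase_duration=min_phase_duration,
    )
    res_imu = pl.estimate_imu(
        stroke.pressure,
        stroke.imu,
        stroke.geometry,
        beta=beta,
        cutoff_pressure=cutoff_pressure,
        phases=res_mocap.phases,
    )
    return res_mocap, res_imu


def compare_pathways(
    strokes,
    beta: float = ori.DEFAULT_BETA,
    n_points: int = 101,
    cutoff_pressure: float | None = 20.0,
    cutoff_coords: float | None = 6.0,
) -> st.AgreementReport:
    """Mocap-vs-IMU agreement over a set of simulated strokes.

    Per stroke, both pathways are estimated on the same synchronized streams
    and the first detected underwater phase is scored (per-phase mean forces
    for ICC/Bland–Altman, time-normalized waveforms for the CMC).
    """
    means_mocap, means_imu, pairs = [], [], []
    for stroke in strokes:
        res_mocap, res_imu = estimate_both(
            stroke, beta=beta, cutoff_pressure=cutoff_pressure, cutoff_coords=cutoff_coords
        )
        if not res_mocap.strokes or not res_imu.strokes:
            continue
        rm, ri = res_mocap.strokes[0], res_imu.strokes[0]
        means_mocap.append(rm.mean_force)
        means_imu.append(ri.mean_force)
        pairs.append((rm.f, ri.f))
    if not means_mocap:
        raise ValueError("no stroke produced a detectable underwater phase")
    return st.agreement_report(means_mocap, means_imu, pairs, n_points=n_points)


def imu_truth_agreement(
    strokes,
    beta: float = ori.DEFAULT_BETA,
    n_points: int = 101,
    cutoff_pressure: float | None = 20.0,
) -> st.AgreementReport:
    """IMU-pathway recovery of the simulator truth.

    Scores per-stroke mean propulsive force and waveform of the IMU estimate
    against the exact truth over the true underwater phase (x = IMU estimate,
    y = truth).
    """
    means_imu, means_true, pairs = [], [], []
    for stroke in strokes:
        truth = stroke.truth
        res_imu = pl.estimate_imu(
            stroke.pressure,
            stroke.imu,
            stroke.geometry,
            beta=beta,
            cutoff_pressure=cutoff_pressure,
            phases=[(truth.entry, truth.exit)],
        )
        ri = res_imu.strokes[0]
        mask = truth.phase_mask()
        means_imu.append(ri.mean_force)
        means_true.append(float(np.mean(truth.f[mask])))
        pairs.append((ri.f, truth.f[mask]))
    return st.agreement_report(means_imu, means_true, pairs, n_points=n_points)
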