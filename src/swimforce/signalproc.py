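"""Zero-phase Butterworth smoothing, residual-analysis cutoff selection, and
multi-stream synchronization.

All recorded streams (pressure, marker coordinates, IMU) are nominally
uniform at 200 Hz.  Smoothing is a dual-pass (forward–backward) Butterworth
filter — 2nd order per pass, 4th-order equivalent magnitude response with
zero phase lag — the convention used with Winter's residual method in
biomechanics.  The cutoff is not pre-warped for the dual pass: ``fc`` is the
per-pass −3 dB frequency, so the dual-pass gain at ``fc`` is 0.5.

The residual-analysis cutoff follows Winter's procedure: the RMS residual
between the raw and filtered signal is computed over a grid of candidate
cutoffs; a straight line is fitted to the noise-dominated high-frequency
tail of the residual curve; the selected cutoff is the grid point where the
residual curve meets the line's zero-frequency intercept (the point at which
signal distortion and residual noise balance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

__all__ = [
    "TimeSeries",
    "lowpass_filter",
    "residual_rms",
    "residual_cutoff",
    "synchronize",
]


@dataclass
class TimeSeries:
    """Uniformly sampled series: times ``t`` (s) and values ``v`` ((N,) or (N, C))."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape[0] != self.t.shape[0]:
            raise ValueError("t and v must have equal length")
        if len(self.t) > 1:
            dts = np.diff(self.t)
            if np.any(dts <= 0):
                raise ValueError("timestamps not strictly increasing")
            if np.ptp(dts) > 1e-6:
                raise ValueError("sampling jitter exceeds 1e-6 s")

    @property
    def fs(self) -> float:
        if len(self.t) < 2:
            raise ValueError("need at least two samples to infer the rate")
        return 1.0 / float(np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return len(self.t)


def _values(x):
    return x.v if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)


def lowpass_filter(x, fc: float, fs: float, order: int = 2):
    """Zero-phase low-pass Butterworth filter (``order`` poles per pass).

    Parameters
    ----------
    x
        Array (filtered along axis 0) or :class:`TimeSeries`.
    fc, fs
        Cutoff and sampling frequencies in Hz; requires ``0 < fc < fs/2``.
    order
        Per-pass filter order; the default dual-pass of two 2nd-order passes
        has a 4th-order-equivalent magnitude response.

    The signal is extended by reflection (``padtype='even'``) over one
    settling length on each side before the forward–backward pass, and the
    output has the same length as the input.
    """
    if not 0 < fc < fs / 2:
        raise ValueError(f"cutoff must satisfy 0 < fc < fs/2, got fc={fc}, fs={fs}")
    v = _values(x)
    b, a = _sig.butter(order, fc / (fs / 2.0))
    out = _sig.filtfilt(b, a, v, axis=0, padtype="even")
    if isinstance(x, TimeSeries):
        return TimeSeries(x.t, out)
    return out


def residual_rms(x, fc: float, fs: float, order: int = 2) -> float:
    """RMS of the residual between a signal and its low-pass filtered version."""
    v = _values(x)
    return float(np.sqrt(np.mean((v - lowpass_filter(v, fc, fs, order)) ** 2)))


def residual_cutoff(
    x,
    fs: float | None = None,
    fc_grid=None,
    noise_fraction: float = 0.4,
    order: int = 2,
) -> float:
    """Winter residual-analysis choice of low-pass cutoff frequency.

    Parameters
    ----------
    x
        Signal array or :class:`TimeSeries` (in which case ``fs`` is inferred).
    fc_grid
        Candidate cutoffs in Hz; default 1–50 Hz in 0.5 Hz steps, clipped to
        the open Nyquist interval.
    noise_fraction
        Fraction of the top of the grid treated as noise-dominated when
        fitting the straight-line tail.

    Returns the grid cutoff whose residual is nearest the fitted line's
    zero-frequency intercept.
    """
    if isinstance(x, TimeSeries):
        fs = x.fs
        x = x.v
    if fs is None:
        raise ValueError("fs is required when x is a bare array")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("residual analysis expects a single-channel signal")
    if np.std(x) == 0:
        raise ValueError("degenerate (zero-variance) signal")
    if fc_grid is None:
        fc_grid = np.arange(1.0, 50.0 + 1e-9, 0.5)
    fc_grid = np.asarray(fc_grid, dtype=float)
    fc_grid = fc_grid[(fc_grid > 0) & (fc_grid < fs / 2.0)]
    if fc_grid.size < 4:
        raise ValueError("cutoff grid needs at least 4 candidates below Nyquist")

    res = np.array([residual_rms(x, fc, fs, order) for fc in fc_grid])

    n_noise = max(2, int(round(noise_fraction * fc_grid.size)))
    tail_f = fc_grid[-n_noise:]
    tail_r = res[-n_noise:]
    slope, intercept = np.polyfit(tail_f, tail_r, 1)
    target = max(float(intercept), 0.0)

    # residual decreases with fc; find where it first drops to the intercept
    eps = 1e-9 * float(np.sqrt(np.mean(x**2)))
    below = np.flatnonzero(res <= target + eps)
    if below.size == 0:
        return float(fc_grid[-1])
    i = int(below[0])
    if i > 0 and abs(res[i - 1] - target) < abs(res[i] - target):
        i -= 1
    return float(fc_grid[i])


def synchronize(streams, pulse_indices):
    """Align streams on a shared synchronization pulse and trim to overlap.

    Each stream is shifted so that its pulse sample sits at ``t = 0`` and all
    streams are trimmed to the common overlapping interval, which is returned
    as a list of equal-length :class:`TimeSeries` on an identical time base.
    """
    streams = list(streams)
    pulse_indices = list(pulse_indices)
    if len(streams) != len(pulse_indices):
        raise ValueError("one pulse index per stream is required")
    if not streams:
        return []
    for k, (s, p) in enumerate(zip(streams, pulse_indices)):
        if p is None:
            raise ValueError(f"missing synchronization pulse for stream {k}")
        if not 0 <= p < len(s):
            raise ValueError(f"pulse index {p} out of range for stream {k}")

    rates = [s.fs for s in streams]
    if max(rates) - min(rates) > 1e-6 * max(rates):
        raise ValueError("streams must share a common sampling rate")
    dt = 1.0 / rates[0]

    start = -min(pulse_indices)  # sample offset relative to the pulse
    end = min(len(s) - 1 - p for s, p in zip(streams, pulse_indices))
    if start > end:
        raise ValueError("streams have no overlapping interval after alignment")

    t_common = np.arange(start, end + 1) * dt
    out = []
    for s, p in zip(streams, pulse_indices):
        sl = slice(p + start, p + end + 1)
        out.append(TimeSeries(t_common, s.v[sl]))
    return out
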