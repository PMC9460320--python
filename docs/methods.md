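# Methods

## Frames and conventions

The global frame is the pool frame: X transverse (right positive), Y the
swimming direction (forward positive), Z vertical (up positive), origin at
the water surface. Quaternions are scalar-first, sensor-to-global: a vector
in the sensor frame maps to the global frame via q ⊗ (0, v) ⊗ q\*, and the
columns of the associated rotation matrix are the sensor axes expressed in
the global frame. The accelerometer measures specific force — a sensor at
rest with its frame aligned to the global frame reads (0, 0, +g),
g = 9.80665 m·s⁻². Gyroscope rates are rad·s⁻¹ internally; the IMU reader
converts deg·s⁻¹ streams when configured.

The palm-orthogonal direction z points out the **dorsal** side of the hand.
This is forced by the sign of the resultant force: FR = Σ Sᵢ(pᵢ − dᵢ) is
positive when palm pressure exceeds dorsal pressure, i.e. when the net force
pushes from the palm toward the dorsum, so F = FR·z_y is positive
(propulsive) exactly when the dorsal normal has a forward component. The
marker construction V₂ × V₁ produces this dorsal normal on both hands (the
V₂ reversal on the left hand compensates chirality), and a hand-mounted IMU
with its z-axis pointing away from the dorsum matches it. In the start pose
(palm down, fingers forward) z ≈ +Z.

## Orientation estimation

The IMU pathway uses the magnetometer-free variant of Madgwick's
gradient-descent fusion. Per sample: the quaternion rate from the gyroscope,
0.5·q ⊗ (0, ω), is corrected by −β times the normalized gradient of the
gravity-alignment objective (the predicted gravity direction in the sensor
frame — the third row of the rotation matrix — minus the normalized
accelerometer reading), then integrated with a first-order step over the
timestamp-derived dt and renormalized. β defaults to 0.033 (the divergence
rate used with this sensor fusion in swimming work); magnetometer fusion is
deliberately excluded (pool machinery disturbs the field), so heading is
unobservable and only gravity-referenced tilt is corrected. Initialization
defaults to the start pose (identity: palm down, z up); an explicit
quaternion or an accelerometer-derived tilt (`q_init="accel"`) is accepted,
the latter being exact for a stationary first sample. Gyro-bias estimation
and long-duration drift correction are out of scope: the intended recordings
are tens of seconds.

Numerical behavior worth knowing: because the correction step has constant
magnitude β·dt, convergence toward a static reference is monotone only down
to a limit cycle of amplitude ≈ β·dt (1.65e−4 rad at 200 Hz); and during
rotation the causal filter carries a small tracking error (≈ 0.5·ω̇·dt² per
step from the endpoint-sampled gyro). On the simulator's default stroke the
peak orientation error is ≈ 1.1°, worth ≈ 0.9% of peak force in F.

## Signal processing

Smoothing is a dual-pass (forward–backward) Butterworth filter, 2nd order
per pass — a 4th-order-equivalent magnitude response with exactly zero phase
lag, the convention tied to Winter's residual method in biomechanics. The
cutoff is the per-pass −3 dB point and is not pre-warped for the dual pass
(gain at the nominal cutoff is 0.5). Edges are extended by reflection before
filtering. Default cutoffs: 6 Hz for marker coordinates, 20 Hz for
pressures, both residual-analysis results for 200 Hz recordings of this
kind; `residual_cutoff` re-derives a cutoff from data by Winter's procedure
(RMS residual over a 1–50 Hz grid, straight-line fit to the top 40% of the
grid, selection where the residual curve meets the line's zero-frequency
intercept). For a noise-free signal the procedure has no noise floor to
intersect; the implementation then returns the first grid point whose
residual is numerically negligible, which can sit well above the signal band
while still passing the signal essentially unchanged.

Streams are aligned on a shared synchronization pulse (one index per
stream), shifted so the pulse sits at t = 0 and trimmed to the overlapping
interval. Marker dropouts of ≤ 5 samples are filled linearly before
filtering; longer occlusions stay invalid rather than fabricating motion.

## Stroke segmentation and per-stroke summaries

Underwater phases run from the downward to the next upward zero crossing of
the third-fingertip height (surface at Z = 0), with crossing times linearly
interpolated. Phases separated by less than a minimum duration (default
0.2 s) are merged and phases shorter than it discarded, which collapses
noise chatter around the surface into single events. The IMU alone cannot
place the hand relative to the surface, so the IMU pathway takes its phases
from the marker pathway, a simulation truth, or manual annotation. Per
stroke, the mean of F over the phase and the full waveform are retained.

## Agreement statistics

* **ICC(2,1)** — single measures, absolute agreement, two-way random
  effects, from the ANOVA mean squares; the absolute-agreement form
  penalizes systematic offsets (a constant shift between methods drives it
  far below 1 where a consistency ICC would stay at 1). The 95% CI is the
  F-based McGraw–Wong interval; agreement labels: < 0.75 low, 0.75–0.90
  medium, > 0.90 good.
* **Bland–Altman** — differences x − y; SD of differences is the n−1
  (mean-square-corrected) sample SD; 95% limits of agreement are
  bias ± 1.96·SD. The confidence bounds for the limits are implemented in
  the published form upper = (D̄ + 1.96·SD) − t·√(3·SD²/n),
  lower = (D̄ − 1.96·SD) + t·√(3·SD²/n) (an inner interval);
  `loa_confidence_intervals(symmetric=True)` gives the conventional
  two-sided intervals. Fixed bias: one-sample t-test of the differences
  against zero. Proportional bias: Pearson correlation between pair means
  and differences. Cohen's d labels: < 0.2 negligible, < 0.5 small, < 0.8
  medium, else large. α = 0.05 throughout, no multiplicity correction.
* **CMC** — on waveforms time-normalized to 101 points (0–100% of the
  phase), computed per stroke for the two methods and summarized by the mean
  across strokes; a negative radicand (anti-phase waveforms) is reported as
  0 and flagged. Labels: 0–0.64 poor, 0.65–0.74 moderate, 0.75–0.84 good,
  0.85–0.94 very good, 0.95–1 excellent.

Degenerate inputs are rejected rather than coerced: zero-variance
differences (t-test, Bland–Altman), zero between-subject variance (ICC),
flat waveform sets (CMC). Identical paired vectors return t = 0, p = 1 by
documented convention.

## Synthetic stroke simulator

The simulator generates the three synchronized 200 Hz recordings from a
closed-form trajectory so that every derived quantity has an exact truth:

* **Orientation** — pitch about global X sweeping −20° → −160° through a C²
  quintic smoothstep over the underwater phase (fingers forward-down at
  entry, backward-up at exit; the palm faces straight backward mid-pull),
  composed with a windowed sinusoidal roll about the finger axis (default
  amplitude 15°). Euler-chain body rates are analytic —
  ω = (φ̇ cos ρ, ρ̇, φ̇ sin ρ) — avoiding numerical differentiation in the
  oracle.
* **Path** — fingertip height is an analytic sinusoid crossing the surface
  exactly at the nominal entry and exit; forward speed 1.2 m·s⁻¹ constant;
  vertical acceleration peaks at ≈ 2.7 m·s⁻². Translational dynamics are
  deliberately modest: orientation estimation, not hydrodynamics, is the
  pathway under test, and a constant-velocity forward path keeps the
  accelerometer's gravity reference exact so fusion errors are attributable
  to the filter itself.
* **Forces** — the resultant force is a half-sine pulse (default peak 20 N)
  over the phase; pressures invert the area equation (equal segment weights)
  about a hydrostatic baseline, so the round trip through the pipeline is
  exact to machine precision without noise.
* **Noise** — white, per channel: gyro 0.01 rad·s⁻¹, accelerometer
  0.1 m·s⁻², markers 2 mm (the order of underwater calibration residuals),
  pressure 0.05 kPa; optional gyro bias and marker dropout default to zero
  (recordings are short; occlusion is a real-data phenomenon the simulator
  only mimics on request). All randomness descends from a single seed
  through spawned generators, so studies are bit-reproducible.
* **Defaults** — 1.2 s underwater phase with 0.4 s leads, consistent in
  order of magnitude with front-crawl strokes at 0.8–1.6 m·s⁻¹; study-level
  simulation draws per-stroke peak force (10–30 N), duration (1.0–1.4 s),
  exit pitch (±10°) and roll amplitude (5–20°).

What passing simulator-based tests does **not** show about real data: no
soft-tissue artifact between skin and sensor, no bubbles or refraction in
the marker images, no turbulence structure in the pressures (white noise
only), no hydrodynamic coupling between hand motion and force, and no
left/right asymmetries beyond geometric mirroring.

## Known limitations

The fused orientation is a causal estimate: on dynamic strokes the IMU
pathway's per-stroke mean force carries a small systematic deficit
(≈ 0.1–0.2% of the mean force under the default noise model), visible in
simulation because the synthetic noise floor is far cleaner than any real
recording chain. Practically it is negligible — two orders of magnitude
below the ≈ 10% between-stroke scatter of real per-stroke means — but a
sufficiently powered bias test against simulation truth will detect it.
Heading drift is uncorrected (no magnetometer), which matters only when the
sensor z-axis leaves the vertical plane of the stroke for long periods.
Areas S₁–S₃ are required inputs (planimetry is an upstream manual step);
resampling of non-200 Hz streams and vendor binary formats are out of
scope.
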