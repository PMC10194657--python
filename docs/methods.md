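# Methods

This note documents the models, parameter choices and numerical decisions
behind stridekit, and what the synthetic-data tests do and do not show.

## Sensor and data model

A `Recording` holds one trial's streams on a single 100 Hz time grid
(float seconds from recording start). Units are SI at ingest: m/s² for
acceleration (gravity included), rad/s for angular rate (dps converted on
load), metres for distance sensors and markers. The 16-channel insole is
grouped into four anatomical regions (heel, midfoot, forefoot, toe; four
elements each) with normalized long-axis coordinates. The distance sensor
saturates at its 0.2 m range limit and is recorded natively at 50 Hz;
resampling to the common grid is linear for continuous channels, with the
in-range flag carried by nearest neighbour.

Quality flags are pure functions of the data: `data_loss` (NaNs in
inertial streams), `sync_failure` (time-base spacing off by more than
1 µs), `pi_degraded` and the reference-side marker-gap flag (> 0.5 s on a
foot marker). The insole-degradation rule — any channel stuck at a
constant for the whole trial or negative-saturated over 10% of samples —
is this package's operationalization of "deteriorated insole data
quality", which has no standard quantitative definition; it is a stand-in,
not a validated criterion.

## The synthetic gait model

The simulator produces every stream from one analytic foot-pose model so
that ground truth is exact by construction:

* **Stance** is an exact zero-velocity dwell: position constant,
  orientation flat, body rates zero. Stance occupies a fixed fraction of
  the stride (default 0.6 of 1.1 s).
* **Swing** advances the foot by the stride length (default 1.2 m) along a
  minimum-jerk horizontal profile (C² at the boundaries, so the
  accelerometer signal starts and ends at zero), with a 5 cm sin² vertical
  lift and a sagittal pitch whose angular rate is −(A·2π/w)·cos(2πτ):
  a prominent positive peak at mid-swing and negative dips at toe-off and
  landing, the structure that foot-worn event detectors exploit. Pitch
  amplitude defaults to 0.35 rad (≈ 20°, peak rate ≈ 5 rad/s ≈ 290 dps,
  well inside a ±2000 dps gyroscope).
* Feet are phase-shifted by half a cycle and staggered by half a stride,
  so each swing leapfrogs the contralateral foot exactly once — this is
  what gives the inter-ankle distance sensor its one in-range dip per
  swing pass (step width 0.1 m, against the 0.2 m range limit).
* A bout of n strides per side is generated as n+1 swings per side (a
  stride is an IC-to-IC interval). Standing separates bouts (5 s default,
  which exceeds the 3 s break threshold) and pads the trial ends.
* The **insole model** loads regions in a physiological roll-over order
  (heel at IC, unloading at 40% of stance; toe from 30% of stance to FC)
  with a fixed 50 ms load/unload ramp, deliberately independent of stance
  duration so that threshold crossings stay within one sample of the true
  event even for the long stance that spans a standing break. Standing
  keeps all regions loaded.
* The **IMU model** is exact kinematics: accelerometer = R(q)ᵀ(a + g·ẑ)
  plus white noise and an optional constant gyro bias. Noise defaults are
  the deployed fleet's reject ceilings (3.31 mg, 0.13 dps) — a
  deliberately conservative, realistic level. The lower-back stream is
  derived from the smoothed mid-foot path plus a 2 cm vertical bob at step
  frequency, enough to exercise the activity recognizer's 0.7 m/s² rule.
* **Markers** are rigid anchor points on the foot poses and a rigid
  4-marker pelvis cluster on the smoothed mid-trajectory.

What the simulator does **not** emulate: soft-tissue artefact, insole
creep and hysteresis, pathological gait signatures (shuffling, festination,
tremor), walking aids, slopes and stairs, magnetometer disturbances, and
marker occlusion patterns other than injected rectangular gaps. Passing
the end-to-end tests therefore demonstrates the pipeline's correctness
under its stated assumptions — clean cyclic gait with genuine mid-stance
stillness — not its clinical accuracy on real cohorts.

An optional curvilinear mode rotates the heading by a fixed angle per
stride. The heading change is applied stepwise at swing onset, so the
gyroscope does not see the yaw transient; stride lengths (horizontal
norms) are unaffected, but this mode should not be used to test yaw
estimation.

## Event detection choices

* Activity windows: 1 s sliding with 50% overlap, merged across gaps
  ≤ 0.5 s. The thresholds (0.7 / 2.1 m/s² on the STD of the acceleration
  norm) are empirically established field constants; the windowing is this
  package's choice.
* Insole binarization: per-channel threshold at baseline + 3·σ with σ the
  median-absolute-deviation of the below-median samples, floored at 5% of
  the channel's dynamic range (an FSR deadband; a pure MAD estimate
  collapses when swing noise is clipped at zero force). 50 ms debounce in
  both directions; a region is active with ≥ 2 of its 4 channels; a
  contact episode is any-region-active, IC at its onset, FC at its offset.
* IMU events: swing peaks found with height ≥ 30% of the interval maximum
  and ≥ 0.4 s separation; FC/IC are the rate minima in the half-windows
  bounded by adjacent peaks. These window constants are deliberate,
  exposed parameters: shank-based variants of this detector exist, but
  the foot-mounted window configuration is not standardized.
* Fusion is greedy one-to-one nearest matching per (side, kind) within
  ±0.25 s, ties toward the earlier IMU event. Matched and insole-only
  events are trusted; IMU-only stance pairs must pass the 100 ms
  double-detector dwell. Alternation is restored by dropping the later of
  two consecutive same-kind events, preferring to keep insole-backed ones.
* Detector normalization ("normalized units") is trial-maximum
  normalization over the active portion, clipped to [0, 1]; 0/0 → 0.

## Trajectory choices

* Madgwick filter: standard IMU variant (gyro quaternion integration with
  a normalized gradient-descent gravity correction), Euler step,
  renormalized each sample; initial tilt from the first 0.5 s of
  accelerometer data. β defaults to 0.1; `optimize_beta` grid-tunes the gain against known stride lengths (ties to the
  smallest β). No magnetometer: yaw is unobservable, which is harmless
  because stride lengths are norms over single-stride segments.
* The gyro bias handed to the filter is the per-axis **median** over all
  ZUPT samples. The median matters: detector smearing leaks a few swing
  samples into the dwell edges, and their large rates would poison a mean
  (a constant fake bias produces a steadily growing tilt error, which was
  the dominant failure mode in development).
* Direct–reverse integration uses trapezoidal quadrature and the linear
  blend v = (1−s)·v_f + s·v_r (algebraically v_f − s·v_f(end)): velocity
  is exactly zero at both anchors by construction, and a constant
  acceleration bias cancels to first order. A sigmoid blend is available
  behind the `weighting` option; linear is the minimal choice and the
  default.
* Stride length is the horizontal (XY) norm of the segment displacement —
  the level-walking convention — with a 3-D option behind a flag.
  A stride is matched to the segment that starts inside it and ends after
  its closing IC (mid-stance to mid-stance); anything else is flagged
  unmeasured and fails stride selection.

## Bout and DMO conventions

The consensus rules fix the filters (0.2–3 s, ≥ 0.15 m, inclusive), the
3 s break, the first/last trimming and the 2+2 eligibility, but leave
three conventions open; this package chooses:

* bout duration = first retained IC to the last retained stride's closing
  IC;
* bout length = the bilateral mean of summed ipsilateral stride lengths
  (both feet traverse the same path);
* trimming removes the chronologically first and last stride of the merged
  bout, one stride total at each end regardless of side — the minimal
  reading of "the first and last stride".

The cadence equation is algebraically 120 / harmonic-mean(duration), which
the tests use as a cross-check.

## Reference (marker) pipeline choices

Gap-filling uses a cubic spline, only for interior gaps < 0.5 s; longer
gaps stay masked and raise the trial flag. Filtering is a 4th-order
Butterworth at 7 Hz applied forward–backward (zero phase, 8th-order
effective magnitude). The pelvis centre is the cluster centroid; the
walking direction is the smoothed horizontal pelvis velocity, held through
pauses. IC/FC candidates are the extrema of the heel/toe anterior
displacement from the pelvis along that direction; each is refined with
the marker's 3-D speed: the still plateau below 5% (IC) or 10% (FC) of the
local peak speed within ±0.15 s identifies the stop/start instant. The
plateau-edge rule replaces a plain speed-minimum search because zero-phase
filtering smears the stop across ~50 ms, leaving a flat near-zero plateau
whose minimum is not at the contact instant.

## Agreement statistics

Quartiles use linear interpolation between order statistics (type 7).
Bout matching requires a temporal overlap of at least 0.5 of the shorter
span, greedy one-to-one by fraction (absolute overlap breaks ties).
Relative errors with a zero reference are excluded with a warning, never
silently. ICC(2,1) is computed from the two-way ANOVA mean squares with
the F-based absolute-agreement CI; the tests pin it to an independent
brute-force ANOVA oracle at 1e-10 and to pingouin's ICC(A,1). The
sample-size planner is the Bonett-type closed form with z = Φ⁻¹(0.975)
and round-to-nearest; for a two-rater design at width 0.1 it yields
{401, 295, 200, 119, 56, 16} bouts for planning ICCs 0.70–0.95.

## Sensor QC

Static STDs are sample STDs (ddof = 1) over the first 100 s. The Allan
deviation is the overlapping estimator on the integrated signal, with a
30-point log-spaced τ grid from 2/fs to a tenth of the record; bias
instability is the raw curve minimum (no 0.664 correction factor — the
IEEE-style definition is used without the correction, and the convention
is stated here so downstream comparisons can adjust). The 60 s spot check
requires a genuinely static segment (accelerometer-norm STD ≤ 2.1 m/s²),
verifies the mean norm within 9.81 ± 0.3 m/s² (tilt-invariant) and the
STDs under 1.15× the fleet ceilings, and returns the per-axis gyro bias.

## Problem sizes and tolerances in the test suite

The default simulated trial is 3 bouts × 10 strides per side (~56 s at
100 Hz), small enough that the full suite runs in well under a minute
while still containing every structural feature (bout breaks, initiation
transients, standing episodes). Frozen expected values follow the
independent oracles that produced them: the 1.00 m displacement pulse is
closed-form; the Allan slope and Gauss–Markov floor use analytic noise
laws (the white + first-order-Markov Allan curve); ICC values use the
ANOVA oracle. Noise-regime assertions (stride-length MAE ≤ 5%, cadence
MAE ≤ 1.5 steps/min) use fixed seeds. Known honest bounds that differ
from idealized figures: per-dwell gravity-residual means reach
~0.08 m/s² at the Madgwick transient (β = 0.1) though the dwell average
is ~0.03; zero-phase filtering is reversal-symmetric only away from the
finite-signal edge transients.

## Known limitations

* The IMU-only event detector assumes the sagittal axis is the body Y
  axis (configurable); it does not auto-detect sensor mounting.
* Stance-time accuracy from the insole model is limited by the roll-over
  pattern's fixed fractions; real FSR timing varies with footwear and
  loading.
* The Madgwick accelerometer correction is active during swing (no
  gating), so aggressive gait transiently tilts the orientation estimate;
  the direct–reverse blend absorbs most, not all, of the resulting
  displacement error.
* The reference pipeline's event refinement constants (speed fractions,
  ±0.15 s window) were chosen against the simulator's kinematics; real
  marker data may need retuning.
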