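# Methods

This note documents the models, numerical choices and limitations behind
`exoassist`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic gait model

The generator replaces human recordings with analytically tractable
periodic signals sampled on a uniform grid (default 500 Hz, the typical
rate of embedded exoskeleton controllers).

* **Hip angle.** `θ(t) = offset + A·cos(2πt/T)` per leg, right leg
  shifted by half a stride, optionally plus a `second_harmonic·A`
  component at twice the stride frequency. Flexion is positive. The
  cosine places peak flexion at the ipsilateral heel-strike and peak
  extension at mid-stride, the qualitative shape of sagittal hip motion.
  Angular velocity is the exact analytic derivative, so filtering and
  power computations can be checked against closed forms.
* **Foot loads.** Each vertical load is a raised-cosine-tapered
  trapezoid: zero in swing, ramps of width `double_contact_fraction` of
  the stride at each end of stance. The plateau height is
  `BW / (2·(stance_fraction − double_contact_fraction))`, which makes
  the stride-averaged total load equal body weight *exactly* (the
  tapered trapezoid has the same mean as the linear one). With the
  default `stance_fraction = 0.55` and `double_contact_fraction = 0.05`
  the two feet's ramps are exactly complementary, so the total load is
  constant through double contact.
* **Events.** The logged heel-strike/toe-off times are the closed-form
  2 %-body-weight crossing times of the ramps, so event logs agree with
  threshold-based contact detection to within one sample by
  construction.
* **Trunk acceleration.** A half-sine transient of amplitude
  `impact_magnitude` (default 5 m/s², width 30 ms) at every heel-strike
  of either foot, on a zero baseline.
* **Per-limb 3-axis GRFs.** Vertical = the load channel; fore-aft = a
  braking-then-propulsion sine over stance scaled by the instantaneous
  load (peak 0.15 BW); mediolateral = 0. This is the minimal structure
  the individual-limbs analyses need.
* **Noise.** Optional additive Gaussian noise per channel group
  (`theta`, `omega`, `grf`, `acc`), applied *after* the analytic
  derivative so velocity noise is independent of angle noise; load noise
  is clipped at zero. Defaults are noise-free, so samplewise invariants
  (load complementarity, event consistency) hold exactly.

Defaults emulate the study conditions the controllers were designed for:
treadmill walking at 4 km/h by a 74 kg adult, stride period 1.1 s
(~109 steps/min), hip excursion −10…+30°. All randomness flows through a
single integer seed; identical parameters give bit-identical output.

**What the generator does not emulate.** The signals are open-loop
playback: the gait does not react to assistance torques, so
assistance-induced changes in cadence, range of motion or phase-estimate
shape — central observations when humans wear the device — cannot occur
here. Passing tests therefore demonstrate correctness of the controllers
and analyses on well-formed gait, not human-in-the-loop behavior, and in
particular not the unstable estimator–wearer interaction loop that can
afflict the phase-based controller on real subjects (degenerate
portraits are flagged and zero torque is emitted, nothing more).

## Reflex controller

* The load-difference `B` is undefined at zero total load. Below
  `load_floor` (default 5 % BW) the last valid `B` is held, initial
  value 0, giving continuous commands through flight phases and sensor
  dropouts with no torque spikes.
* The 20 Hz first-order smoother is a Butterworth design via bilinear
  transform with pre-warping, so the −3 dB point lands exactly at the
  cut-off; DC gain is exactly 1, hence filtered commands never exceed
  the raw gain bound. The filter state is exposed, and chunked
  (streaming) application equals one-pass application sample-for-sample.
* Smoothing is applied to the per-leg torque commands, not to `B`
  before the gain branching; away from the zero crossing the two
  orderings coincide, and filtering the commands is what a hardware
  implementation bounds.
* Optional quantization to the 25 mN·m resolution of typical drive
  electronics is off by default (it is hardware emulation, not part of
  the control law).

## Phase-based controller

* **Portrait axes.** The integral is on the abscissa and the angle on
  the ordinate. For any periodic signal the curve (signal, integral) is
  traversed counter-clockwise; with the angle on the ordinate the
  traversal is clockwise and the polar angle decreases by 2π per stride,
  which is the orientation the two-branch `p_GC` formula assumes.
* **Drift and normalization.** The running integral of an angle with
  nonzero mean drifts linearly, so the angle is de-meaned over a
  trailing window of one stride *before* integration; both axes are
  then de-meaned and scaled to unit peak-to-peak over the same window.
  The window is initialized to 1.2 s and set to the median detected
  stride period when at least two heel-strikes are found. The first
  window or two of the portrait are warm-up; accuracy contracts apply
  from the third stride on.
* **Boundary of the `p_GC` formula.** The literal second branch yields
  1 at `ϕ = ϕ_HS`; the implementation returns 0 there (a heel-strike
  starts the cycle), and values that round to exactly 1.0 are clamped
  into [0, 1).
* **Heel-strike detector.** Candidates are trunk-acceleration peaks
  more than 1.5 m/s² above the record median that fall within ±50 ms of
  a flexion-to-extension zero-crossing of the ipsilateral hip velocity;
  a refractory period of 50 % of the running stride-period estimate
  (median of recent accepted intervals, initialized to 1.2 s) suppresses
  doubles. All thresholds are configuration-exposed. The velocity
  gating is what rejects the contralateral impacts that share the trunk
  channel; strongly multi-harmonic hip velocities can create additional
  zero-crossings near mid-stride, which the refractory period then has
  to absorb — a known limitation of the simple detector.
* **Warm-up.** Before the first detected heel-strike there is no anchor;
  torque is held at zero and the interval is flagged invalid (phase
  traces are still emitted from an initial anchor `ϕ_HS = ϕ[0]`).
* **Profile.** `t_peak` is the plateau midpoint; with the defaults the
  extension bout therefore spans 82.5→22.5 %GC (wrapping) and the
  flexion bout 32.5→72.5 %GC, disjoint by construction (overlap is
  rejected at construction). Each leg anchors the same profile to its
  own heel-strikes; no explicit 50 %GC inter-leg offset is applied.
  Zero-amplitude bouts are allowed (null profile).

## Mechanical analyses

* The "sixth-order zero-lag" kinematic filter is an order-3 Butterworth
  applied forward-backward; the per-pass cut-off is multiplied by
  `(√2 − 1)^(−1/6) ≈ 1.158` so the *combined* −3 dB point lands at the
  requested 6 Hz.
* Work uses the trapezoidal rule on the uniform grid; positive and
  negative parts are integrated separately, so
  `work_pos − |work_neg| = work_net` holds to rounding on every stride.
  Following the symmetric-gait convention, pipeline summaries report the
  left leg.
* Strides are segmented at consecutive left heel-strikes; offline
  contact detection uses a 2 % BW rising threshold with a 1 % BW
  hysteresis band. Cadence is `60·(n_steps − 1) / (t_last − t_first)`
  over the merged step onsets of both feet (at least 4 required).
* Profiles are averaged on a 101-point 0–100 %GC grid, the standard
  gait-analysis convention (linear interpolation per stride; population
  SD across strides).

## Individual limbs method

Axis order is [fore-aft, mediolateral, vertical]. COM acceleration is
`(F_total − m·g·ẑ)/m`; velocity is its trapezoidal integral over the
integer-stride span (inputs are truncated to it, with a warning), with
constants pinning the span-averaged velocity to `(belt_speed, 0, 0)` —
the standard treadmill adaptation of the overground method, exposed as
configuration. Limb power is the per-sample dot product of that limb's
GRF with the COM velocity, so `P_L + P_R = F_total · v_COM` exactly.
Double contact is both loads above 2 % BW; the leading limb is the foot
with the more recent contact onset; windows truncated by the record
edges are skipped. Only the per-window extrema are reported, not
step-to-step transition work integrals.

## Metabolics

Outlier removal compares each breath's V'O2 against a centered 30-breath
moving mean. The deviation scale is by default the whole-record SD: on
the short records of steady-state trials a 30-sample windowed SD is both
noisy and biased by the candidate breath itself, which makes the "3 SD"
rule behave far from its nominal Gaussian tail probability (≈0.27 %);
with the record-level SD the rule is close to nominal. The windowed SD
remains available (`sd_scope="local"`). Removal is a single pass.

The gross rate averages V'O2/V'CO2 over the final 60 s and converts via
a linear Brockway-type energy equivalent, `E[kJ] = 16.58·V_O2[L] +
4.51·V_CO2[L]`, with both coefficients configurable; the net rate
subtracts the standing baseline, and rates are normalized by body mass
(W/kg). A respiratory exchange ratio ≥ 1 triggers a warning (the
conversion assumes predominantly aerobic metabolism). No interpolation
to uniform time and no on/off-kinetics modeling is attempted.

## Problem sizes

Tests and the acceptance script run on desk-scale inputs chosen to make
every contract measurable: 20–100 strides of 500 Hz synthetic gait
(11–110 s records), 10⁴-point parameter grids, and 10⁴ synthetic breaths
for the outlier-rate check. All stochastic checks are seeded.

## Known limitations

* Open-loop playback only (no musculoskeletal response, no belt
  dynamics, no 3D kinematics beyond the sagittal hip angle).
* The heel-strike detector is deliberately simple; gaits whose hip
  velocity has strong harmonics near mid-stride may need tighter
  association windows or a longer refractory fraction.
* Decomposition of combined force-plate signals into per-limb GRFs is
  out of scope; per-limb forces are taken as inputs.
* The energy-equivalent coefficients are a documented convention, not a
  reproduction of any specific tabulation.
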