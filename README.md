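# exoassist

Assistance controllers for sagittal-plane hip exoskeletons, with a
synthetic treadmill-gait generator and the standard outcome analyses used
to evaluate them. The package is aimed at wearable-robotics researchers
who want to study, test or extend gait-synchronized torque controllers
without hardware in the loop.

## The two controllers

**Simple Reflex Controller (SRC, implicit synchronization).** The only
input is the pair of vertical ground reaction forces under the feet,
`W_l` and `W_r`. A memoryless, dimensionless load-difference map

    B(W_l, W_r) = (W_l − W_r) / (W_l + W_r)

is +1 in left single support, −1 in right single support, and sweeps
between them during each ~100 ms double-contact weight transfer. Each
hip's torque command scales `B` by an extension gain during stance and a
flexion gain during swing (extension negative, flexion positive):

    T_L = −B·τ_ext  if B > 0,  else −B·τ_flx
    T_R =  B·τ_ext  if B < 0,  else  B·τ_flx

with defaults τ_ext = 135.0 mN·m/kg and τ_flx = 67.5 mN·m/kg, multiplied
by body mass. Commands are smoothed by a causal first-order IIR low-pass
(f_c = 20 Hz) to avoid torque steps. Because `B` is normalized, the load
sensors need neither calibration nor symmetry; any common scale cancels.

**Hip-Phase-based Torque profile controller (HPT, explicit
synchronization).** The gait-cycle fraction `p_GC ∈ [0, 1)` is estimated
without a clock from the phase portrait of the hip flexion/extension
angle `θ_hip` plotted against its running time integral (both axes
windowed-de-meaned and normalized to unit peak-to-peak). The portrait is
traversed clockwise once per stride, so its polar angle `ϕ` decreases by
2π per cycle, and

    p_GC = (ϕ_HS − ϕ)/2π          if 0 ≤ ϕ < ϕ_HS
    p_GC = (2π + ϕ_HS − ϕ)/2π     if ϕ_HS ≤ ϕ < 2π

where the anchor `ϕ_HS` is re-captured at every heel-strike, detected
from trunk vertical acceleration transients gated by the hip's
flexion-to-extension velocity zero-crossing. Between events `p_GC` is
clamped non-decreasing. The estimate indexes a predefined torque profile
of two semi-trapezoidal bouts (rise `T_r`, plateau, 5 %GC fall), by
default an extension bout (135.0 mN·m/kg peak centered at 10 %GC) and a
flexion bout (67.5 mN·m/kg centered at 60 %GC), both with total duration
40 %GC and 20 %GC rise. Left and right legs run independent estimators.

## Outcome analyses

* exoskeleton power (torque × hip angular velocity) and per-stride
  positive / negative / net work, after zero-lag 6th-order Butterworth
  filtering of the kinematics at 6 Hz;
* cadence from 2 %-body-weight rising crossings of the per-foot loads;
* external mechanical power of each limb on the center of mass
  (individual limbs method) with the trailing-limb push-off maximum and
  leading-limb weight-acceptance minimum per double-contact phase;
* net metabolic rate from breath-by-breath gas exchange (3-SD outlier
  removal, last-minute steady-state average, energy-equivalent-of-oxygen
  conversion, standing-baseline subtraction).

The bundled generator produces periodic walking signals (anti-phase
quasi-sinusoidal hip angles, cosine-tapered trapezoidal foot loads,
heel-strike trunk transients, optional 3-axis per-limb GRFs) with exact
ground-truth events, so every analysis can be tested against closed
forms. The signals are open-loop playback: they do not adapt to the
commanded torques.

## Worked example

```sh
exoassist run --seed 1 --outdir demo
```

simulates 30 s of treadmill walking (74 kg, 4 km/h, 1.1 s strides), runs
the reflex controller, and writes torque/phase series, 101-point
stride-normalized profiles and `demo/summary.json`. With this seed the
summary reports:

* `cadence_steps_per_min`: **109.1** — two steps per 1.1 s stride;
* 27 analyzed left strides with mean per-stride exoskeleton work
  `mean_pos` **10.27 J**, `mean_neg` **0.05 J**, `mean_net` **10.21 J**
  — assistance is almost entirely aligned with the hip motion
  (predominantly positive power), with small negative-work episodes in
  late stance and late swing, as expected from the reactive map;
* individual-limbs-method double-contact peaks `mean_P_max_trail_W`
  **+64.3 W** (trailing-limb push-off) and `mean_P_min_lead_W`
  **−66.1 W** (leading-limb weight acceptance).

The same pipeline with `controller: hpt` in a YAML config exercises the
phase-based controller and additionally writes the per-leg
`time, ϕ, ϕ_HS, p_GC` traces. Library use mirrors the CLI:
`generate_gait`, `run_src`, `run_hpt`, `stride_work`, … are plain
functions on NumPy arrays (see `docs/methods.md`).

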