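"""Synthetic treadmill-gait signal generator.

Produces the multi-channel signals the assistance controllers and the
outcome analyses consume -- hip flexion/extension angles and angular
velocities, per-foot vertical loads, vertical trunk acceleration and
(optionally) 3-axis per-limb ground reaction forces -- as smooth periodic
waveforms with known ground-truth gait events.  This replaces human
recordings: the signals are open-loop playback, so they do not react to
assistance torques.

Conventions
-----------
* Hip angles/velocities: flexion positive, extension negative (deg, deg/s).
* Loads: vertical GRF per foot, newtons, >= 0.
* The left heel-strike defines 0% of the left gait cycle; the right leg is
  shifted by half a stride (anti-phase).
* Per-foot load is a raised-cosine-tapered trapezoid: zero in swing, ramps
  of width ``double_contact_fraction`` of the stride at each end of stance.
  The plateau height is chosen in closed form so the stride-averaged total
  load equals body weight exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ParameterError

G = 9.80665  # m/s^2, standard gravity

#: channels that accept additive Gaussian noise, with their units
NOISE_CHANNELS = ("theta", "omega", "grf", "acc")

#: fraction of body weight used to define foot-contact onset/offset
CONTACT_THRESHOLD = 0.02


@dataclass(frozen=True)
class GaitParams:
    """Parameters of the synthetic walking pattern.

    Defaults emulate steady treadmill walking at 4 km/h by an average-mass
    adult: stride period 1.1 s (~109 steps/min), stance 55% of the stride
    with two 5% double-contact transitions, hip excursion -10..+30 deg.
    """

    stride_period: float = 1.1  # s
    stance_fraction: float = 0.55  # of stride
    double_contact_fraction: float = 0.05  # of stride, per transition
    hip_amplitude: float = 20.0  # deg
    hip_offset: float = 10.0  # deg
    second_harmonic: float = 0.0  # fraction of hip_amplitude (0.3 typical)
    body_mass: float = 74.0  # kg
    body_weight: float | None = None  # N; default body_mass * g
    belt_speed: float = 4.0 / 3.6  # m/s (4 km/h)
    fore_aft_amplitude: float = 0.15  # peak A-P force, fraction of BW
    impact_magnitude: float = 5.0  # m/s^2, trunk transient at heel-strike
    impact_width: float = 0.03  # s, heel-strike transient duration
    noise_sd: Mapping[str, float] | None = None  # keys in NOISE_CHANNELS
    include_grf3d: bool = True
    sample_rate: float = 500.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stride_period > 0:
            raise ParameterError("stride_period must be > 0")
        if not 0 < self.stance_fraction < 1:
            raise ParameterError("stance_fraction must be in (0, 1)")
        if not self.double_contact_fraction > 0:
            raise ParameterError("double_contact_fraction must be > 0")
        if not 2 * self.double_contact_fraction < self.stance_fraction:
            raise ParameterError(
                "2*double_contact_fraction must be < stance_fraction"
            )
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be > 0")
        if self.body_mass <= 0:
            raise ParameterError("body_mass must be > 0")
        if self.noise_sd is not None:
            unknown = set(self.noise_sd) - set(NOISE_CHANNELS)
            if unknown:
                raise ParameterError(
                    f"unknown noise channels {sorted(unknown)}; "
                    f"expected subset of {NOISE_CHANNELS}"
                )

    @property
    def weight(self) -> float:
        """Body weight in newtons."""
        return self.body_weight if self.body_weight is not None else self.body_mass * G

    def with_(self, **kw) -> "GaitParams":
        return replace(self, **kw)


@dataclass
class GaitSignals:
    """Synchronized multi-channel gait time series on a uniform grid."""

    time: np.ndarray  # s
    theta_hip_L: np.ndarray  # deg
    theta_hip_R: np.ndarray  # deg
    omega_hip_L: np.ndarray  # deg/s
    omega_hip_R: np.ndarray  # deg/s
    W_l: np.ndarray  # N
    W_r: np.ndarray  # N
    a_z: np.ndarray  # m/s^2
    sample_rate: float
    grf3d_L: np.ndarray | None = None  # (n, 3) N, [fore-aft, ML, vertical]
    grf3d_R: np.ndarray | None = None
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    CORE_CHANNELS = (
        "time",
        "theta_hip_L",
        "theta_hip_R",
        "omega_hip_L",
        "omega_hip_R",
        "W_l",
        "W_r",
        "a_z",
    )

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class EventLog:
    """Ground-truth gait events (seconds)."""

    heelstrikes_L: np.ndarray
    heelstrikes_R: np.ndarray
    toeoffs_L: np.ndarray
    toeoffs_R: np.ndarray

    def __post_init__(self) -> None:
        for name in ("heelstrikes_L", "heelstrikes_R", "toeoffs_L", "toeoffs_R"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if np.any(np.diff(arr) <= 0):
                raise ParameterError(f"{name} must be strictly increasing")
        merged = np.sort(
            np.concatenate(
                [self.heelstrikes_L, self.heelstrikes_R]
            )
        )
        labels = np.concatenate(
            [
                np.zeros(len(self.heelstrikes_L)),
                np.ones(len(self.heelstrikes_R)),
            ]
        )[np.argsort(np.concatenate([self.heelstrikes_L, self.heelstrikes_R]))]
        if len(merged) > 1 and np.any(np.diff(labels) == 0):
            raise ParameterError("left/right heel-strikes must alternate")


def _load_waveform(u: np.ndarray, stance: float, dc: float) -> np.ndarray:
    """Normalized (0..1) single-foot vertical load vs stride fraction u."""
    w = np.zeros_like(u)
    rise = u < dc
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / dc))
    plateau = (u >= dc) & (u < stance - dc)
    w[plateau] = 1.0
    fall = (u >= stance - dc) & (u < stance)
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (u[fall] - (stance - dc)) / dc))
    return w


def _contact_crossing_offset(params: GaitParams, plateau: float) -> float:
    """Stride fraction after ramp start where the load crosses 2% BW."""
    level = CONTACT_THRESHOLD * params.weight / plateau
    level = min(max(level, 0.0), 1.0)
    return params.double_contact_fraction * math.acos(1.0 - 2.0 * level) / math.pi


def generate_gait(params: GaitParams, duration: float) -> tuple[GaitSignals, EventLog]:
    """Generate a synthetic walking record and its ground-truth events.

    The hip angle is ``offset + A*cos(2*pi*t/T)`` (optionally plus a
    ``second_harmonic * A`` component at twice the stride frequency), peaking
    in flexion at each ipsilateral heel-strike and reaching peak extension at
    mid-stride, with the right leg in anti-phase.  Angular velocity is the
    analytic derivative.  Identical ``(params, duration)`` give bit-identical
    output.
    """
    if not duration >= 2 * params.stride_period:
        raise ParameterError("duration must cover at least two strides")

    T = params.stride_period
    fs = params.sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    A = params.hip_amplitude
    h = params.second_harmonic
    w0 = 2.0 * np.pi / T

    def theta(tt: np.ndarray) -> np.ndarray:
        return params.hip_offset + A * np.cos(w0 * tt) + h * A * np.cos(2 * w0 * tt)

    def omega(tt: np.ndarray) -> np.ndarray:
        return -A * w0 * np.sin(w0 * tt) - 2 * h * A * w0 * np.sin(2 * w0 * tt)

    theta_L = theta(t)
    theta_R = theta(t - T / 2.0)
    omega_L = omega(t)
    omega_R = omega(t - T / 2.0)

    s, dc = params.stance_fraction, params.double_contact_fraction
    plateau = params.weight / (2.0 * (s - dc))  # stride-mean total = BW
    u_L = np.mod(t / T, 1.0)
    u_R = np.mod(t / T - 0.5, 1.0)
    W_l = plateau * _load_waveform(u_L, s, dc)
    W_r = plateau * _load_waveform(u_R, s, dc)

    # ground-truth events: analytic 2% body-weight crossing of the ramps
    du = _contact_crossing_offset(params, plateau)
    k_max = int(math.ceil(duration / T)) + 1
    k = np.arange(k_max)
    hs_L = (k + du) * T
    to_L = (k + s - du) * T
    hs_R = (k + 0.5 + du) * T
    to_R = (k + 0.5 + s - du) * T
    hs_L = hs_L[hs_L < duration]
    to_L = to_L[to_L < duration]
    hs_R = hs_R[hs_R < duration]
    to_R = to_R[to_R < duration]

    # trunk vertical acceleration: zero baseline + half-sine impact pulses
    a_z = np.zeros(n)
    width = max(params.impact_width, 2.0 / fs)
    for t_e in np.concatenate([hs_L, hs_R]):
        i0 = int(np.ceil(t_e * fs))
        i1 = min(int(np.floor((t_e + width) * fs)) + 1, n)
        if i0 >= n:
            continue
        tt = t[i0:i1] - t_e
        a_z[i0:i1] += params.impact_magnitude * np.sin(np.pi * tt / width)

    grf3d_L = grf3d_R = None
    if params.include_grf3d:
        amp = params.fore_aft_amplitude * params.weight

        def fore_aft(u: np.ndarray, w_norm: np.ndarray) -> np.ndarray:
            f = np.zeros_like(u)
            st = u < s
            f[st] = -amp * np.sin(2.0 * np.pi * u[st] / s)
            return f * w_norm

        grf3d_L = np.column_stack(
            [fore_aft(u_L, W_l / plateau), np.zeros(n), W_l]
        )
        grf3d_R = np.column_stack(
            [fore_aft(u_R, W_r / plateau), np.zeros(n), W_r]
        )

    # additive noise, applied after the analytic derivative so that angular
    # velocity noise is independent of angle noise
    sd = dict(params.noise_sd or {})
    rng = np.random.default_rng(params.seed)
    if sd.get("theta", 0.0) > 0:
        theta_L = theta_L + rng.normal(0.0, sd["theta"], n)
        theta_R = theta_R + rng.normal(0.0, sd["theta"], n)
    if sd.get("omega", 0.0) > 0:
        omega_L = omega_L + rng.normal(0.0, sd["omega"], n)
        omega_R = omega_R + rng.normal(0.0, sd["omega"], n)
    if sd.get("grf", 0.0) > 0:
        W_l = np.clip(W_l + rng.normal(0.0, sd["grf"], n), 0.0, None)
        W_r = np.clip(W_r + rng.normal(0.0, sd["grf"], n), 0.0, None)
        if grf3d_L is not None:
            grf3d_L[:, 2] = W_l
            grf3d_R[:, 2] = W_r
    if sd.get("acc", 0.0) > 0:
        a_z = a_z + rng.normal(0.0, sd["acc"], n)

    signals = GaitSignals(
        time=t,
        theta_hip_L=theta_L,
        theta_hip_R=theta_R,
        omega_hip_L=omega_L,
        omega_hip_R=omega_R,
        W_l=W_l,
        W_r=W_r,
        a_z=a_z,
        sample_rate=fs,
        grf3d_L=grf3d_L,
        grf3d_R=grf3d_R,
    )
    events = EventLog(
        heelstrikes_L=hs_L,
        heelstrikes_R=hs_R,
        toeoffs_L=to_L,
        toeoffs_R=to_R,
    )
    return signals, events


def sinusoid_preset(**overrides) -> GaitParams:
    """Pure-sinusoid hip-angle preset (no second harmonic, no noise)."""
    return GaitParams(second_harmonic=0.0, noise_sd=None, **overrides)
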