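"""Hip-Phase-based Torque profile controller (HPT).

Gait phase is estimated without a clock, from the polar angle of the
hip-angle phase portrait.  The portrait plots the hip flexion/extension
angle against its running time integral (the integral, a quadrature
companion of the quasi-sinusoidal hip angle, is preferred over the
derivative because integration suppresses high-frequency noise and
impact-induced oscillations).  With the angle on the ordinate and the
integral on the abscissa the portrait is traversed clockwise, so the polar
angle phi decreases by 2*pi per stride.  The gait-cycle fraction is the
normalized distance swept since the last heel-strike:

    p_GC = (phi_HS - phi) / (2*pi)         if 0 <= phi < phi_HS
    p_GC = (2*pi + phi_HS - phi) / (2*pi)  if phi_HS <= phi < 2*pi

where phi_HS, the anchor, is re-captured at every detected heel-strike
(p_GC resets to 0 there).  Between heel-strikes p_GC is clamped to be
non-decreasing, so local non-monotonicity of phi cannot move the profile
backwards.  The estimate drives a predefined two-bout semi-trapezoidal
torque profile (one extension burst around early stance, one flexion burst
around swing initiation), evaluated independently per leg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate as spi
from scipy import signal as sps

from .errors import DegeneratePortraitError, ParameterError
from .reflex import TorqueCommand
from .synth import GaitSignals

TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# torque profile
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutParams:
    """One semi-trapezoidal assistance bout on the 0-100 %GC circle.

    ``t_peak`` is the midpoint of the plateau; the plateau length is
    ``T_tot - T_r - fall``.  The bout therefore rises over ``T_r`` %GC,
    holds ``tau_peak`` (negated for extension bouts), and falls back to
    zero over ``fall`` %GC, wrapping around the cycle boundary if needed.
    """

    tau_peak: float  # mN·m/kg, >= 0
    t_peak: float  # %GC, midpoint of the plateau
    T_tot: float = 40.0  # %GC
    T_r: float = 20.0  # %GC
    fall: float = 5.0  # %GC
    direction: str = "extension"

    def __post_init__(self) -> None:
        if self.tau_peak < 0:
            raise ParameterError("tau_peak must be >= 0")
        if self.direction not in ("extension", "flexion"):
            raise ParameterError("direction must be 'extension' or 'flexion'")
        if not (self.T_r + self.fall <= self.T_tot <= 100.0):
            raise ParameterError("require T_r + fall <= T_tot <= 100")

    @property
    def plateau(self) -> float:
        return self.T_tot - self.T_r - self.fall

    @property
    def start(self) -> float:
        """%GC at which the rise begins (may wrap)."""
        return (self.t_peak - self.plateau / 2.0 - self.T_r) % 100.0

    @property
    def sign(self) -> float:
        return -1.0 if self.direction == "extension" else 1.0

    def support(self) -> list[tuple[float, float]]:
        """Nonzero support as unwrapped [a, b) intervals within [0, 100)."""
        a, b = self.start, self.start + self.T_tot
        if b <= 100.0:
            return [(a, b)]
        return [(a, 100.0), (0.0, b - 100.0)]

    def evaluate(self, p_gc) -> np.ndarray:
        """Signed torque (mN·m/kg) at gait-cycle fraction(s) in [0, 1)."""
        p = np.asarray(p_gc, dtype=float)
        u = (p * 100.0 - self.start) % 100.0
        out = np.zeros_like(u)
        if self.T_r > 0:
            rise = u < self.T_r
            out[rise] = u[rise] / self.T_r
        on = (u >= self.T_r) & (u < self.T_r + self.plateau)
        out[on] = 1.0
        if self.fall > 0:
            f0 = self.T_r + self.plateau
            falling = (u >= f0) & (u < f0 + self.fall)
            out[falling] = 1.0 - (u[falling] - f0) / self.fall
        result = self.sign * self.tau_peak * out
        return float(result) if np.isscalar(p_gc) else result


def default_extension_bout() -> BoutParams:
    return BoutParams(tau_peak=135.0, t_peak=10.0, direction="extension")


def default_flexion_bout() -> BoutParams:
    return BoutParams(tau_peak=67.5, t_peak=60.0, direction="flexion")


@dataclass(frozen=True)
class HeelStrikeConfig:
    """Thresholds of the trunk-acceleration + hip-velocity event detector."""

    az_threshold: float = 1.5  # m/s^2 above baseline (median)
    assoc_window: float = 0.05  # s around the flexion-to-extension crossing
    refractory_fraction: float = 0.5  # of the running stride-period estimate
    init_period: float = 1.2  # s, stride-period estimate before any events


def _intervals_overlap(a: list[tuple[float, float]],
                       b: list[tuple[float, float]]) -> bool:
    return any(x0 < y1 and y0 < x1 for x0, x1 in a for y0, y1 in b)


@dataclass(frozen=True)
class HptParams:
    """Full HPT configuration: two bouts, body mass, event detection."""

    extension_bout: BoutParams = field(default_factory=default_extension_bout)
    flexion_bout: BoutParams = field(default_factory=default_flexion_bout)
    body_mass: float = 74.0  # kg
    hs_config: HeelStrikeConfig = field(default_factory=HeelStrikeConfig)
    portrait_window: float = 1.2  # s, initial normalization window

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ParameterError("body_mass must be > 0")
        if (self.extension_bout.tau_peak > 0 and self.flexion_bout.tau_peak > 0
                and _intervals_overlap(self.extension_bout.support(),
                                       self.flexion_bout.support())):
            raise ParameterError("extension and flexion bout supports overlap")

    def with_(self, **kw) -> "HptParams":
        return replace(self, **kw)


def hpt_profile(p_gc, params: HptParams):
    """Total profile torque (mN·m/kg): sum of the two bouts, wrap-around."""
    p = np.mod(np.asarray(p_gc, dtype=float), 1.0)
    out = params.extension_bout.evaluate(p) + params.flexion_bout.evaluate(p)
    return float(out) if np.isscalar(p_gc) else out


# --------------------------------------------------------------------------
# phase portrait and phase estimation
# --------------------------------------------------------------------------

def build_phase_portrait(theta_hip, sample_rate: float, window: float = 1.2):
    """Normalized (integral, angle) portrait of the hip angle.

    The running time integral of the angle drifts with any nonzero mean, so
    both axes are de-meaned over a trailing window of roughly one stride
    and scaled to unit peak-to-peak amplitude over that window.  Returns
    ``(portrait_x, portrait_y)`` with the integral on x and the angle on y,
    the orientation for which the portrait of forward walking is traversed
    clockwise.
    """
    theta = np.asarray(theta_hip, dtype=float)
    w = max(int(round(window * sample_rate)), 2)
    if len(theta) < w:
        raise ParameterError("series shorter than the normalization window")
    if np.ptp(theta) < 1e-9 * max(1.0, float(np.max(np.abs(theta)))):
        raise DegeneratePortraitError("hip angle has zero peak-to-peak amplitude")

    def rolling(x: np.ndarray):
        roll = pd.Series(x).rolling(w, min_periods=2)
        return roll.mean().to_numpy(), (roll.max() - roll.min()).to_numpy()

    def scale(x: np.ndarray) -> np.ndarray:
        mean, ptp = rolling(x)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (x - mean) / ptp

    # integrate the de-meaned angle: any nonzero mean would make the raw
    # integral drift linearly, which no subsequent de-meaning can normalize
    theta_mean, _ = rolling(theta)
    centered = theta - np.where(np.isfinite(theta_mean), theta_mean, theta[0])
    integral = spi.cumulative_trapezoid(centered, dx=1.0 / sample_rate,
                                        initial=0.0)
    return scale(integral), scale(theta)


def phase_angle(portrait_x, portrait_y):
    """Four-quadrant polar angle of portrait points, wrapped to [0, 2*pi).

    NaN portrait samples (normalization warm-up) yield NaN; an exact origin
    point is degenerate.
    """
    x = np.asarray(portrait_x, dtype=float)
    y = np.asarray(portrait_y, dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    if np.any(finite & (x == 0.0) & (y == 0.0)):
        raise DegeneratePortraitError("portrait point at the origin")
    phi = np.mod(np.arctan2(y, x), TWO_PI)
    return float(phi) if np.isscalar(portrait_x) else phi


def estimate_pGC(phi, phi_HS):
    """Gait-cycle fraction from the current and heel-strike phase angles.

    Both angles are in [0, 2*pi); phi decreases over the cycle, so the
    fraction is the clockwise arc swept since the anchor, normalized by a
    full turn.  Returns a value in [0, 1); exactly 0 at phi == phi_HS.
    """
    phi = np.asarray(phi, dtype=float)
    phi_HS = np.asarray(phi_HS, dtype=float)
    first = (phi_HS - phi) / TWO_PI
    second = (TWO_PI + phi_HS - phi) / TWO_PI
    out = np.where(phi <= phi_HS, first, second)
    # phi infinitesimally past phi_HS can round to exactly 1.0; keep [0, 1)
    out = np.where(out >= 1.0, np.nextafter(1.0, 0.0), out)
    return float(out) if out.ndim == 0 else out


@dataclass
class PhaseState:
    """Instantaneous phase-estimator state for one leg."""

    phi: float = 0.0
    phi_HS: float = 0.0
    p_GC: float = 0.0


def update_phase(state: PhaseState, phi: float, hs_event: bool) -> PhaseState:
    """Advance the estimator by one sample.

    On a heel-strike the anchor is re-captured and p_GC resets to 0;
    otherwise p_GC is the raw estimate clamped to be non-decreasing.
    """
    if hs_event:
        return PhaseState(phi=phi, phi_HS=phi, p_GC=0.0)
    p = max(state.p_GC, estimate_pGC(phi, state.phi_HS))
    return PhaseState(phi=phi, phi_HS=state.phi_HS, p_GC=p)


# --------------------------------------------------------------------------
# heel-strike detection
# --------------------------------------------------------------------------

def detect_heelstrike(omega_hip, a_z, sample_rate: float,
                      config: HeelStrikeConfig | None = None) -> np.ndarray:
    """Detect heel-strikes from hip angular velocity and trunk acceleration.

    A candidate is a trunk-acceleration peak exceeding the baseline (median)
    by ``az_threshold`` that falls within ``assoc_window`` of a
    flexion-to-extension (positive-to-negative) zero-crossing of the hip
    angular velocity.  A refractory period -- a fraction of the running
    stride-period estimate -- suppresses double detections.  Returns event
    times in seconds; an empty array on degenerate input is valid.
    """
    cfg = config if config is not None else HeelStrikeConfig()
    omega = np.asarray(omega_hip, dtype=float)
    a_z = np.asarray(a_z, dtype=float)
    n = len(a_z)
    baseline = float(np.median(a_z))
    peaks, _ = sps.find_peaks(a_z, height=baseline + cfg.az_threshold)
    if len(peaks) == 0:
        return np.array([])

    down = np.where((omega[:-1] > 0) & (omega[1:] <= 0))[0] + 1
    if len(down) == 0:
        return np.array([])
    crossing_t = down / sample_rate

    events: list[float] = []
    intervals: list[float] = []
    period = cfg.init_period
    for p in peaks:
        t_p = p / sample_rate
        if np.min(np.abs(crossing_t - t_p)) > cfg.assoc_window:
            continue
        if events:
            gap = t_p - events[-1]
            if gap < cfg.refractory_fraction * period:
                continue
            intervals.append(gap)
            period = float(np.median(intervals[-5:]))
        events.append(t_p)
    return np.asarray(events)


# --------------------------------------------------------------------------
# full controller
# --------------------------------------------------------------------------

@dataclass
class PhaseSeries:
    """Per-leg phase-estimator traces emitted by :func:`run_hpt`."""

    time: np.ndarray
    phi_L: np.ndarray
    phi_HS_L: np.ndarray
    p_GC_L: np.ndarray
    phi_R: np.ndarray
    phi_HS_R: np.ndarray
    p_GC_R: np.ndarray
    heelstrikes_L: np.ndarray
    heelstrikes_R: np.ndarray
    valid_L: np.ndarray  # False during warm-up / degenerate intervals
    valid_R: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time,
            "phi_L": self.phi_L, "phi_HS_L": self.phi_HS_L,
            "p_GC_L": self.p_GC_L,
            "phi_R": self.phi_R, "phi_HS_R": self.phi_HS_R,
            "p_GC_R": self.p_GC_R,
        })


def _run_leg(theta, omega, a_z, sample_rate, params: HptParams):
    cfg = params.hs_config
    n = len(theta)
    hs_times = detect_heelstrike(omega, a_z, sample_rate, cfg)
    if len(hs_times) >= 2:
        window = float(np.median(np.diff(hs_times)))
    else:
        window = params.portrait_window
    try:
        px, py = build_phase_portrait(theta, sample_rate, window)
        phi = phase_angle(px, py)
    except DegeneratePortraitError:
        warnings.warn("degenerate phase portrait; leg torque set to zero")
        zeros = np.zeros(n)
        return zeros, zeros, zeros, zeros, np.array([]), np.zeros(n, bool)

    hs_idx = np.unique(np.clip(np.round(hs_times * sample_rate).astype(int), 0, n - 1))
    # segment-wise: within a segment the anchor is constant and p_GC is a
    # running maximum of the raw estimate, which matches per-sample updates
    phi_hs_series = np.empty(n)
    p = np.empty(n)
    valid = np.zeros(n, dtype=bool)
    finite = np.isfinite(phi)
    phi_filled = np.where(finite, phi, 0.0)
    bounds = [0, *hs_idx.tolist(), n]
    anchor = phi_filled[0]
    for seg, (i0, i1) in enumerate(zip(bounds[:-1], bounds[1:])):
        if i1 <= i0:
            continue
        if seg > 0:  # segment opens at a heel-strike: re-anchor, reset
            anchor = phi_filled[i0]
        raw = estimate_pGC(phi_filled[i0:i1], anchor)
        if seg > 0:
            raw[0] = 0.0
            valid[i0:i1] = True
        p[i0:i1] = np.maximum.accumulate(raw)
        phi_hs_series[i0:i1] = anchor
    valid &= finite
    torque = np.where(valid, hpt_profile(p, params), 0.0)
    return torque, phi_filled, phi_hs_series, p, hs_times, valid


def run_hpt(signals: GaitSignals, params: HptParams | None = None
            ) -> tuple[TorqueCommand, PhaseSeries]:
    """Run the HPT controller over a record, independently per leg.

    Composition per leg: heel-strike detection -> phase portrait -> polar
    angle -> anchored %GC estimate (monotone between events, reset at
    events) -> profile lookup -> scale by body mass.  Torque is held at
    zero until the first detected heel-strike of that leg and over
    degenerate-portrait intervals (flagged in ``valid_*``).
    """
    params = params if params is not None else HptParams()
    fs = signals.sample_rate
    out_L = _run_leg(signals.theta_hip_L, signals.omega_hip_L, signals.a_z,
                     fs, params)
    out_R = _run_leg(signals.theta_hip_R, signals.omega_hip_R, signals.a_z,
                     fs, params)
    scale = 1e-3 * params.body_mass  # mN·m/kg -> N·m
    cmd = TorqueCommand(time=signals.time,
                        T_L=out_L[0] * scale, T_R=out_R[0] * scale)
    phases = PhaseSeries(
        time=signals.time,
        phi_L=out_L[1], phi_HS_L=out_L[2], p_GC_L=out_L[3],
        phi_R=out_R[1], phi_HS_R=out_R[2], p_GC_R=out_R[3],
        heelstrikes_L=out_L[4], heelstrikes_R=out_R[4],
        valid_L=out_L[5], valid_R=out_R[5],
    )
    return cmd, phases
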