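"""Simple Reflex Controller (SRC): load-difference reflex mapping.

The controller maps the per-foot vertical loads to hip torque commands
through the normalized load difference

    B(W_l, W_r) = (W_l - W_r) / (W_l + W_r)

which is +1 in left single support, -1 in right single support, and sweeps
between the two during each double-contact weight transfer.  B is scaled by
the extension gain during stance and the flexion gain during swing of each
leg (extension torques negative, flexion positive), and the resulting
commands are smoothed by a causal first-order IIR low-pass filter.

Because B is dimensionless, the loads only need to be proportional to the
true GRFs: any common positive scale factor cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InputError, ParameterError
from .synth import G, GaitSignals

#: torque resolution of typical exoskeleton drive electronics, N·m
TORQUE_RESOLUTION = 0.025


@dataclass(frozen=True)
class SrcParams:
    """Reflex-controller gains and filter settings.

    ``tau_ext``/``tau_flx`` are the per-unit-mass assistance amplitudes
    (mN·m/kg); defaults are the moderate values used for naive walkers
    (extension twice the flexion amplitude).  ``load_floor`` is the total
    load, as a fraction of body weight, below which B is held at its last
    valid value (the ratio is undefined at zero total load).
    """

    tau_ext: float = 135.0  # mN·m/kg
    tau_flx: float = 67.5  # mN·m/kg
    f_c: float = 20.0  # Hz
    body_mass: float = 74.0  # kg
    load_floor: float = 0.05  # fraction of body weight
    quantize: bool = False  # round output to drive resolution

    def __post_init__(self) -> None:
        if self.tau_ext <= 0 or self.tau_flx <= 0:
            raise ParameterError("tau_ext and tau_flx must be > 0")
        if self.f_c <= 0:
            raise ParameterError("f_c must be > 0")
        if self.load_floor < 0:
            raise ParameterError("load_floor must be >= 0")
        if self.body_mass <= 0:
            raise ParameterError("body_mass must be > 0")


@dataclass
class SrcState:
    """Streaming state: last valid B and per-leg filter memories."""

    last_valid_B: float = 0.0
    filter_state_L: np.ndarray | None = None
    filter_state_R: np.ndarray | None = None


@dataclass
class TorqueCommand:
    """Per-leg commanded torque series (N·m; extension < 0, flexion > 0)."""

    time: np.ndarray
    T_L: np.ndarray
    T_R: np.ndarray
    units: str = "N.m"
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "T_L": self.T_L, "T_R": self.T_R})


def compute_B(W_l, W_r, state: SrcState | None = None,
              load_floor_abs: float = 0.0):
    """Normalized load difference with hold below the load floor.

    Accepts scalars or aligned arrays.  Where ``W_l + W_r`` falls below
    ``load_floor_abs`` the last valid value is held (initially
    ``state.last_valid_B``, default 0); ``state.last_valid_B`` is updated to
    the value at the final sample.
    """
    W_l = np.asarray(W_l, dtype=float)
    W_r = np.asarray(W_r, dtype=float)
    if np.any(W_l < 0) or np.any(W_r < 0):
        raise InputError("vertical loads must be non-negative")
    scalar = W_l.ndim == 0
    W_l, W_r = np.atleast_1d(W_l), np.atleast_1d(W_r)
    state = state if state is not None else SrcState()

    total = W_l + W_r
    valid = total >= max(load_floor_abs, np.finfo(float).tiny)
    B = np.empty_like(total)
    np.divide(W_l - W_r, total, out=B, where=valid)
    # hold last valid value across invalid samples (forward fill)
    idx = np.where(valid, np.arange(len(B)), -1)
    idx = np.maximum.accumulate(idx)
    B = np.where(idx >= 0, B[np.maximum(idx, 0)], state.last_valid_B)
    state.last_valid_B = float(B[-1])
    return float(B[0]) if scalar else B


def src_raw_torques(B, params: SrcParams):
    """Unfiltered per-unit-mass torques (mN·m/kg) from the load difference.

    Left:  -B * tau_ext for B > 0, else -B * tau_flx.
    Right:  B * tau_ext for B < 0, else  B * tau_flx.
    """
    B = np.asarray(B, dtype=float)
    T_L = np.where(B > 0, -B * params.tau_ext, -B * params.tau_flx)
    T_R = np.where(B < 0, B * params.tau_ext, B * params.tau_flx)
    if B.ndim == 0:
        return float(T_L), float(T_R)
    return T_L, T_R


def design_iir_lowpass(f_c: float, sample_rate: float):
    """First-order Butterworth low-pass (bilinear transform, pre-warped).

    The -3 dB point lands exactly at ``f_c``; DC gain is exactly 1.
    """
    if not 0 < f_c < sample_rate / 2:
        raise ParameterError("f_c must lie in (0, sample_rate/2)")
    return sps.butter(1, f_c, fs=sample_rate)


def iir_lowpass(x, f_c: float, sample_rate: float,
                state: np.ndarray | None = None, return_state: bool = False):
    """Causal first-order IIR low-pass; stateful for streaming use.

    ``state`` is the filter memory returned by a previous call (initial
    rest if None), so chunked and one-pass application agree
    sample-for-sample.
    """
    b, a = design_iir_lowpass(f_c, sample_rate)
    x = np.asarray(x, dtype=float)
    zi = np.zeros(1) if state is None else np.asarray(state, dtype=float)
    y, zf = sps.lfilter(b, a, x, zi=zi)
    return (y, zf) if return_state else y


def run_src(signals: GaitSignals, params: SrcParams,
            state: SrcState | None = None) -> TorqueCommand:
    """Run the reflex controller over a full record.

    Per-sample composition: load difference -> gain branching -> first-order
    low-pass (each leg filtered independently) -> scale by body mass.
    """
    state = state if state is not None else SrcState()
    floor_abs = params.load_floor * params.body_mass * G
    B = compute_B(signals.W_l, signals.W_r, state, floor_abs)
    T_L_raw, T_R_raw = src_raw_torques(B, params)
    T_L, state.filter_state_L = iir_lowpass(
        T_L_raw, params.f_c, signals.sample_rate,
        state.filter_state_L, return_state=True)
    T_R, state.filter_state_R = iir_lowpass(
        T_R_raw, params.f_c, signals.sample_rate,
        state.filter_state_R, return_state=True)
    scale = 1e-3 * params.body_mass  # mN·m/kg -> N·m
    T_L = T_L * scale
    T_R = T_R * scale
    if params.quantize:
        T_L = np.round(T_L / TORQUE_RESOLUTION) * TORQUE_RESOLUTION
        T_R = np.round(T_R / TORQUE_RESOLUTION) * TORQUE_RESOLUTION
    return TorqueCommand(time=signals.time, T_L=T_L, T_R=T_R)
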