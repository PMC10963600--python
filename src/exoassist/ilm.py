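"""Individual limbs method (ILM): external mechanical power of each leg.

The external power a limb exerts on the center of mass (COM) is the dot
product of that limb's 3-axis ground reaction force with the COM velocity.
COM acceleration follows from the total GRF and gravity; velocity comes
from trapezoidal integration over an integer number of strides with
per-axis constants chosen for treadmill walking: stride-averaged vertical
and mediolateral velocity zero, fore-aft velocity equal to the belt speed.

During each double-contact phase the trailing limb (the foot about to
leave, loaded the longer) produces the positive push-off power peak and
the leading limb (the foot that just landed) the negative
weight-acceptance peak; these per-cycle extrema are the reported outcome.

Axis convention: columns [fore-aft, mediolateral, vertical].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as spi

from .errors import InputError
from .mech import StrideSegment, detect_foot_contacts
from .synth import G


@dataclass
class ComState:
    """COM kinematics over an integer-stride span of the record."""

    time: np.ndarray
    a_com: np.ndarray  # (n, 3) m/s^2
    v_com: np.ndarray  # (n, 3) m/s
    i0: int  # span of the original record covered
    i1: int


def com_velocity(total_grf, body_mass: float, belt_speed: float,
                 strides: list[StrideSegment], sample_rate: float) -> ComState:
    """COM acceleration and velocity from the total 3-axis GRF.

    The record is truncated (with a warning) to the integer-stride span
    defined by ``strides``; the integration constants pin the
    stride-averaged velocity to (belt_speed, 0, 0).
    """
    F = np.asarray(total_grf, dtype=float)
    if F.ndim != 2 or F.shape[1] != 3:
        raise InputError("total_grf must be an (n, 3) array")
    if not strides:
        raise InputError("at least one complete stride is required")
    i0, i1 = strides[0].i0, strides[-1].i1
    if i0 > 0 or i1 < len(F):
        warnings.warn("truncating record to integer number of strides")
    F = F[i0:i1]
    a = F / body_mass
    a[:, 2] -= G
    v = spi.cumulative_trapezoid(a, dx=1.0 / sample_rate, initial=0.0, axis=0)
    v -= v.mean(axis=0)
    v[:, 0] += belt_speed
    time = np.arange(i0, i1) / sample_rate
    return ComState(time=time, a_com=a, v_com=v, i0=i0, i1=i1)


def limb_power(grf_limb, com: ComState) -> np.ndarray:
    """Per-sample external power of one limb: GRF . v_COM (W)."""
    F = np.asarray(grf_limb, dtype=float)
    if F.ndim != 2 or F.shape[1] != 3:
        raise InputError("grf_limb must be an (n, 3) array")
    F = F[com.i0:com.i1]
    return np.einsum("ij,ij->i", F, com.v_com)


@dataclass
class IlmPeaks:
    """Double-contact power extrema: trailing max / leading min per cycle."""

    P_max_trail: np.ndarray = field(default_factory=lambda: np.array([]))
    P_min_lead: np.ndarray = field(default_factory=lambda: np.array([]))
    window_times: list[tuple[float, float]] = field(default_factory=list)

    @property
    def mean_trail(self) -> float:
        return float(np.mean(self.P_max_trail)) if len(self.P_max_trail) else float("nan")

    @property
    def mean_lead(self) -> float:
        return float(np.mean(self.P_min_lead)) if len(self.P_min_lead) else float("nan")


def _double_contact_windows(loaded_l: np.ndarray, loaded_r: np.ndarray
                            ) -> list[tuple[int, int]]:
    both = loaded_l & loaded_r
    edges = np.flatnonzero(np.diff(both.astype(int)))
    starts = edges[np.diff(both.astype(int))[edges] > 0] + 1
    ends = edges[np.diff(both.astype(int))[edges] < 0] + 1
    if both[0]:
        starts = np.concatenate([[0], starts])
    if both[-1]:
        ends = np.concatenate([ends, [len(both)]])
    return list(zip(starts.tolist(), ends.tolist()))


def double_contact_peaks(power_L, power_R, W_l, W_r, sample_rate: float,
                         body_weight: float | None = None,
                         threshold: float = 0.02) -> IlmPeaks:
    """Extract the trailing-limb maximum and leading-limb minimum power in
    every double-contact phase (both vertical loads above the threshold).

    The leading limb of a window is the foot whose contact onset is more
    recent at the window start.  Edge-truncated windows are skipped.  An
    empty result (with a warning) is valid when no double contact exists.
    """
    power_L = np.asarray(power_L, dtype=float)
    power_R = np.asarray(power_R, dtype=float)
    W_l = np.asarray(W_l, dtype=float)[: len(power_L)]
    W_r = np.asarray(W_r, dtype=float)[: len(power_R)]
    if body_weight is None:
        body_weight = float(np.mean(W_l + W_r))
    thr = threshold * body_weight
    onsets_l, _ = detect_foot_contacts(W_l, sample_rate, body_weight, threshold)
    onsets_r, _ = detect_foot_contacts(W_r, sample_rate, body_weight, threshold)

    peaks = IlmPeaks()
    trail_max, lead_min = [], []
    windows = _double_contact_windows(W_l > thr, W_r > thr)
    for s, e in windows:
        if s == 0 or e == len(W_l):  # truncated at a record edge
            continue
        t_start = s / sample_rate
        last_l = onsets_l[onsets_l <= t_start + 1e-9]
        last_r = onsets_r[onsets_r <= t_start + 1e-9]
        if len(last_l) == 0 or len(last_r) == 0:
            continue
        # newer onset = leading foot
        if last_l[-1] > last_r[-1]:
            lead, trail = power_L[s:e], power_R[s:e]
        else:
            lead, trail = power_R[s:e], power_L[s:e]
        trail_max.append(float(np.max(trail)))
        lead_min.append(float(np.min(lead)))
        peaks.window_times.append((s / sample_rate, e / sample_rate))
    if not trail_max:
        warnings.warn("no double-contact phases found")
    peaks.P_max_trail = np.asarray(trail_max)
    peaks.P_min_lead = np.asarray(lead_min)
    return peaks
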