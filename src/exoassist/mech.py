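"""Mechanical outcome analyses: filtering, stride segmentation, exoskeleton
power/work, cadence, and stride-normalized average profiles.

Offline processing mirrors standard gait-lab practice: kinematics are
low-pass filtered with a zero-lag (forward-backward) Butterworth filter,
records are cut into strides at consecutive ipsilateral heel-strikes,
per-stride quantities are integrated with the trapezoidal rule, and
profiles are time-normalized to a 101-point 0-100 %GC grid for averaging.
"""

from __future__ import annotations

import warnings

import numpy as np
from dataclasses import dataclass, field
from scipy import signal as sps

from .errors import DataLengthError, InsufficientDataError, ParameterError

DEG2RAD = np.pi / 180.0
PCT_GRID = np.linspace(0.0, 100.0, 101)


@dataclass(frozen=True)
class StrideSegment:
    """One stride: the half-open sample range between ipsilateral heel-strikes."""

    start: float  # s
    end: float  # s
    i0: int  # first sample index
    i1: int  # one past the last sample index

    def __post_init__(self) -> None:
        if not (self.end > self.start and self.i1 > self.i0):
            raise ParameterError("stride segment must have end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def segment_strides(heelstrikes, sample_rate: float, n_samples: int
                    ) -> list[StrideSegment]:
    """Partition the record into strides between consecutive heel-strikes."""
    hs = np.asarray(heelstrikes, dtype=float)
    segments = []
    for t0, t1 in zip(hs[:-1], hs[1:]):
        i0 = int(np.ceil(t0 * sample_rate - 1e-9))
        i1 = int(np.ceil(t1 * sample_rate - 1e-9))
        i0, i1 = max(i0, 0), min(i1, n_samples)
        if i1 > i0:
            segments.append(StrideSegment(start=t0, end=t1, i0=i0, i1=i1))
    return segments


def detect_foot_contacts(W, sample_rate: float, body_weight: float,
                         threshold: float = 0.02, hysteresis: float = 0.01
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Contact onsets/offsets from a vertical load channel.

    Contact begins at a rising crossing of ``threshold``x body weight and
    ends when the load drops below ``threshold - hysteresis``; the
    hysteresis band suppresses chatter near the threshold.  Returns
    (onset_times, offset_times).
    """
    W = np.asarray(W, dtype=float)
    hi = threshold * body_weight
    lo = (threshold - hysteresis) * body_weight
    onsets, offsets = [], []
    in_contact = W[0] >= hi
    for i in range(1, len(W)):
        if not in_contact and W[i] >= hi > W[i - 1]:
            in_contact = True
            onsets.append(i / sample_rate)
        elif in_contact and W[i] < lo <= W[i - 1]:
            in_contact = False
            offsets.append(i / sample_rate)
    return np.asarray(onsets), np.asarray(offsets)


def zero_lag_lowpass(x, cutoff: float, sample_rate: float, order: int = 6):
    """Zero-lag Butterworth low-pass via forward-backward filtering.

    ``order`` is the total (combined) order; each pass uses order/2.  The
    per-pass cut-off is pre-corrected so the combined -3 dB point lands at
    the requested ``cutoff``.
    """
    if order % 2 != 0 or order <= 0:
        raise ParameterError("order must be a positive even integer")
    if not 0 < cutoff < sample_rate / 2:
        raise ParameterError("cutoff must lie in (0, sample_rate/2)")
    n = order // 2
    # two passes of an order-n Butterworth: |H|^4... combined -3 dB at
    # wc * (sqrt(2)-1)^(1/(2n)); invert to hit the requested cutoff
    correction = (np.sqrt(2.0) - 1.0) ** (-1.0 / (2.0 * n))
    fc = min(cutoff * correction, 0.999 * sample_rate / 2)
    b, a = sps.butter(n, fc, fs=sample_rate)
    x = np.asarray(x, dtype=float)
    warmup = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= 3 * warmup:
        raise DataLengthError(
            f"series of length {len(x)} too short for order-{order} "
            f"zero-lag filtering (need > {3 * warmup})")
    return sps.filtfilt(b, a, x)


def instantaneous_power(torque, omega, omega_unit: str = "deg/s"):
    """Exoskeleton power as torque times hip angular velocity (W).

    ``omega`` in deg/s is converted to rad/s internally.  Assistance
    aligned with the motion gives positive power.  A heuristic warning is
    emitted when the velocity magnitudes suggest a unit mix-up.
    """
    torque = np.asarray(torque, dtype=float)
    omega = np.asarray(omega, dtype=float)
    med = float(np.median(np.abs(omega[np.abs(omega) > 0]))) if np.any(omega) else 0.0
    if omega_unit == "deg/s":
        if 0.0 < med < 1.0:
            warnings.warn("median |omega| < 1 deg/s: radians passed as degrees?")
        omega = omega * DEG2RAD
    elif omega_unit == "rad/s":
        if med > 50.0:
            warnings.warn("median |omega| > 50 rad/s: degrees passed as radians?")
    else:
        raise ParameterError("omega_unit must be 'deg/s' or 'rad/s'")
    return torque * omega


@dataclass
class WorkSummary:
    """Per-stride positive/negative/net exoskeleton work (J).

    ``work_neg`` holds absolute values; ``work_net = work_pos - work_neg``
    to integration tolerance on every stride.
    """

    work_pos: np.ndarray = field(default_factory=lambda: np.array([]))
    work_neg: np.ndarray = field(default_factory=lambda: np.array([]))
    work_net: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_strides(self) -> int:
        return len(self.work_pos)

    def _stat(self, arr, fn):
        return float(fn(arr)) if len(arr) else float("nan")

    @property
    def mean_pos(self):
        return self._stat(self.work_pos, np.mean)

    @property
    def mean_neg(self):
        return self._stat(self.work_neg, np.mean)

    @property
    def mean_net(self):
        return self._stat(self.work_net, np.mean)

    def as_dict(self) -> dict:
        return {
            "n_strides": self.n_strides,
            "work_pos": self.work_pos.tolist(),
            "work_neg": self.work_neg.tolist(),
            "work_net": self.work_net.tolist(),
            "mean_pos": self.mean_pos,
            "mean_neg": self.mean_neg,
            "mean_net": self.mean_net,
            "sd_pos": self._stat(self.work_pos, lambda a: np.std(a, ddof=0)),
            "sd_neg": self._stat(self.work_neg, lambda a: np.std(a, ddof=0)),
            "sd_net": self._stat(self.work_net, lambda a: np.std(a, ddof=0)),
        }


def stride_work(power, sample_rate: float,
                strides: list[StrideSegment]) -> WorkSummary:
    """Trapezoidal per-stride integrals of the positive, negative and full
    power signal.  Empty stride list gives an empty summary."""
    power = np.asarray(power, dtype=float)
    dt = 1.0 / sample_rate
    pos, neg, net = [], [], []
    for seg in strides:
        p = power[seg.i0:seg.i1]
        pos.append(np.trapezoid(np.maximum(p, 0.0), dx=dt))
        neg.append(abs(np.trapezoid(np.minimum(p, 0.0), dx=dt)))
        net.append(np.trapezoid(p, dx=dt))
    return WorkSummary(work_pos=np.asarray(pos), work_neg=np.asarray(neg),
                       work_net=np.asarray(net))


def cadence_from_grf(W_l, W_r, sample_rate: float,
                     body_weight: float | None = None) -> float:
    """Cadence (steps/min) from rising 2%-body-weight crossings of the
    per-foot vertical GRFs.

    With ``body_weight`` unset, it is estimated as the record mean of the
    total vertical load (valid for records spanning whole strides).
    """
    W_l = np.asarray(W_l, dtype=float)
    W_r = np.asarray(W_r, dtype=float)
    if body_weight is None:
        body_weight = float(np.mean(W_l + W_r))
    if body_weight <= 0:
        raise InsufficientDataError("cannot estimate body weight from zero loads")
    steps = np.sort(np.concatenate([
        detect_foot_contacts(W_l, sample_rate, body_weight)[0],
        detect_foot_contacts(W_r, sample_rate, body_weight)[0],
    ]))
    if len(steps) < 4:
        raise InsufficientDataError(
            f"need at least 4 steps, found {len(steps)}")
    return 60.0 * (len(steps) - 1) / (steps[-1] - steps[0])


def resample_strides(x, strides: list[StrideSegment],
                     n_points: int = 101) -> np.ndarray:
    """Time-normalize a signal to ``n_points`` per stride (rows = strides)."""
    x = np.asarray(x, dtype=float)
    grid = np.linspace(0.0, 1.0, n_points)
    rows = []
    for seg in strides:
        chunk = x[seg.i0:seg.i1]
        u = np.linspace(0.0, 1.0, len(chunk))
        rows.append(np.interp(grid, u, chunk))
    return np.asarray(rows)


def average_profile(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Across-stride mean and population SD of a resampled profile."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return rows.mean(axis=0), rows.std(axis=0, ddof=0)
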