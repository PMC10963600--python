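"""Columnar text I/O for gait signals, events, torques and profiles.

All files are comma-separated text with a header row; units and provenance
(seed, config hash) are carried in ``#``-prefixed comment lines before the
header.  Round trips are lossless at full double precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError
from .synth import EventLog, GaitSignals

_UNITS = {
    "time": "s",
    "theta_hip_L": "deg",
    "theta_hip_R": "deg",
    "omega_hip_L": "deg/s",
    "omega_hip_R": "deg/s",
    "W_l": "N",
    "W_r": "N",
    "a_z": "m/s^2",
    "grf_L_x": "N",
    "grf_L_y": "N",
    "grf_L_z": "N",
    "grf_R_x": "N",
    "grf_R_y": "N",
    "grf_R_z": "N",
    "T_L": "N.m",
    "T_R": "N.m",
    "phi": "rad",
    "phi_HS": "rad",
    "p_GC": "",
}

_REQUIRED = (
    "time",
    "theta_hip_L",
    "theta_hip_R",
    "omega_hip_L",
    "omega_hip_R",
    "W_l",
    "W_r",
    "a_z",
)

_FLOAT_FMT = "%.17g"


def _write_frame(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        for col in frame.columns:
            unit = _UNITS.get(col, "")
            fh.write(f"# unit: {col} {unit}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_frame(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body and not body.startswith("unit:"):
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            frame = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.ParserError as exc:  # ragged rows etc.
            raise FormatError(f"{path}: {exc}") from exc
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    return frame, meta


def signals_to_frame(signals: GaitSignals) -> pd.DataFrame:
    cols = {name: getattr(signals, name) for name in _REQUIRED}
    if signals.grf3d_L is not None:
        for i, ax in enumerate("xyz"):
            cols[f"grf_L_{ax}"] = signals.grf3d_L[:, i]
            cols[f"grf_R_{ax}"] = signals.grf3d_R[:, i]
    cols.update(signals.extra)
    return pd.DataFrame(cols)


def frame_to_signals(frame: pd.DataFrame, sample_rate: float | None = None) -> GaitSignals:
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required channel(s): {', '.join(missing)}")
    time = frame["time"].to_numpy(float)
    if sample_rate is None:
        dt = np.diff(time)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError("time grid is not uniform; cannot infer sample rate")
        sample_rate = 1.0 / dt[0]
    grf_cols = [f"grf_{side}_{ax}" for side in "LR" for ax in "xyz"]
    has_grf = all(c in frame.columns for c in grf_cols)
    known = set(_REQUIRED) | set(grf_cols)
    extra = {
        c: frame[c].to_numpy(float) for c in frame.columns if c not in known
    }
    return GaitSignals(
        time=time,
        theta_hip_L=frame["theta_hip_L"].to_numpy(float),
        theta_hip_R=frame["theta_hip_R"].to_numpy(float),
        omega_hip_L=frame["omega_hip_L"].to_numpy(float),
        omega_hip_R=frame["omega_hip_R"].to_numpy(float),
        W_l=frame["W_l"].to_numpy(float),
        W_r=frame["W_r"].to_numpy(float),
        a_z=frame["a_z"].to_numpy(float),
        sample_rate=sample_rate,
        grf3d_L=(
            np.column_stack([frame[f"grf_L_{ax}"].to_numpy(float) for ax in "xyz"])
            if has_grf
            else None
        ),
        grf3d_R=(
            np.column_stack([frame[f"grf_R_{ax}"].to_numpy(float) for ax in "xyz"])
            if has_grf
            else None
        ),
        extra=extra,
    )


def write_signals(signals: GaitSignals, path, meta: dict | None = None) -> None:
    """Write a :class:`GaitSignals` record as commented CSV."""
    _write_frame(signals_to_frame(signals), path, meta)


def read_signals(path) -> GaitSignals:
    """Read a signals CSV written by :func:`write_signals`.

    Unknown extra columns are preserved in ``signals.extra`` and ignored by
    the controllers.  A missing required channel raises :class:`FormatError`.
    """
    frame, _ = _read_frame(path)
    return frame_to_signals(frame)


def write_events(events: EventLog, path, meta: dict | None = None) -> None:
    rows = []
    for label, arr in (
        ("HS_L", events.heelstrikes_L),
        ("HS_R", events.heelstrikes_R),
        ("TO_L", events.toeoffs_L),
        ("TO_R", events.toeoffs_R),
    ):
        rows.extend((t, label) for t in arr)
    rows.sort()
    frame = pd.DataFrame(rows, columns=["time", "event"])
    _write_frame(frame, path, meta)


def read_events(path) -> EventLog:
    frame, _ = _read_frame(path)
    for col in ("time", "event"):
        if col not in frame.columns:
            raise FormatError(f"missing required column '{col}'")

    def pick(label: str) -> np.ndarray:
        return frame.loc[frame["event"] == label, "time"].to_numpy(float)

    return EventLog(
        heelstrikes_L=pick("HS_L"),
        heelstrikes_R=pick("HS_R"),
        toeoffs_L=pick("TO_L"),
        toeoffs_R=pick("TO_R"),
    )


def write_table(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write any analysis table (torques, phase series) as commented CSV."""
    _write_frame(frame, path, meta)


def read_table(path) -> pd.DataFrame:
    frame, _ = _read_frame(path)
    return frame


def export_profile(grid: np.ndarray, mean: np.ndarray, sd: np.ndarray, path,
                   meta: dict | None = None) -> None:
    """Export a stride-normalized average profile as ``%GC,mean,sd`` CSV.

    The grid must be the standard 101-point 0-100 %GC grid.
    """
    if len(grid) != 101 or len(mean) != 101 or len(sd) != 101:
        raise FormatError("profile export requires the 101-point %GC grid")
    frame = pd.DataFrame({"%GC": grid, "mean": mean, "sd": sd})
    _write_frame(frame, path, meta)
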