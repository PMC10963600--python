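"""End-to-end pipeline: simulate -> control -> analyze -> export."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import gaitio, ilm, mech
from .config import RunConfig
from .phase import run_hpt
from .reflex import run_src

log = logging.getLogger("exoassist")


def _export_mean_profile(x, strides, path, meta) -> tuple[np.ndarray, np.ndarray]:
    rows = mech.resample_strides(x, strides, 101)
    mean, sd = mech.average_profile(rows)
    gaitio.export_profile(mech.PCT_GRID, mean, sd, path, meta)
    return mean, sd


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write the output bundle.

    Steps: simulate gait -> run the selected controller -> stride-segment
    -> exoskeleton power/work -> cadence and ILM double-contact peaks ->
    write torque CSV, phase CSV (HPT only), a JSON summary and
    stride-normalized 101-point average profiles for hip angle, torque and
    power.  Outputs embed the seed and config hash; identical configs
    reproduce identical files.
    """
    from .synth import generate_gait  # local import keeps module load light

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config": config.config_hash()}
    gait = config.gait.with_(seed=config.seed)

    log.info("simulate: %.1f s at %.0f Hz", config.duration, gait.sample_rate)
    signals, events = generate_gait(gait, config.duration)
    gaitio.write_signals(signals, outdir / "signals.csv", meta)
    gaitio.write_events(events, outdir / "events.csv", meta)

    log.info("control: %s", config.controller)
    phases = None
    if config.controller == "src":
        cmd = run_src(signals,
                      dataclasses.replace(config.src, body_mass=gait.body_mass))
    else:
        cmd, phases = run_hpt(signals, config.hpt.with_(body_mass=gait.body_mass))
    gaitio.write_table(cmd.to_frame(), outdir / "torques.csv", meta)
    if phases is not None:
        gaitio.write_table(phases.to_frame(), outdir / "phase.csv", meta)

    summary: dict = {"seed": config.seed, "config": config.config_hash(),
                     "controller": config.controller}
    written = {"signals": "signals.csv", "events": "events.csv",
               "torques": "torques.csv"}
    if phases is not None:
        written["phase"] = "phase.csv"

    if config.analyze_mech:
        fs = signals.sample_rate
        theta_f = mech.zero_lag_lowpass(signals.theta_hip_L, 6.0, fs)
        omega_f = mech.zero_lag_lowpass(signals.omega_hip_L, 6.0, fs)
        onsets, _ = mech.detect_foot_contacts(signals.W_l, fs, gait.weight)
        strides = mech.segment_strides(onsets, fs, len(signals))
        power = mech.instantaneous_power(cmd.T_L, omega_f)
        work = mech.stride_work(power, fs, strides)
        cadence = mech.cadence_from_grf(signals.W_l, signals.W_r, fs,
                                        gait.weight)
        log.info("mech: %d strides, cadence %.1f steps/min",
                 work.n_strides, cadence)
        summary["cadence_steps_per_min"] = cadence
        summary["work_left_J"] = work.as_dict()
        for name, series in (("hip_angle", theta_f), ("torque", cmd.T_L),
                             ("power", power)):
            _export_mean_profile(series, strides, outdir / f"profile_{name}.csv",
                                 meta)
            written[f"profile_{name}"] = f"profile_{name}.csv"

        if config.analyze_ilm and signals.grf3d_L is not None:
            total = signals.grf3d_L + signals.grf3d_R
            com = ilm.com_velocity(total, gait.body_mass, gait.belt_speed,
                                   strides, fs)
            p_l = ilm.limb_power(signals.grf3d_L, com)
            p_r = ilm.limb_power(signals.grf3d_R, com)
            peaks = ilm.double_contact_peaks(
                p_l, p_r, signals.W_l[com.i0:com.i1],
                signals.W_r[com.i0:com.i1], fs, gait.weight)
            log.info("ilm: %d double-contact phases", len(peaks.P_max_trail))
            summary["ilm"] = {
                "P_max_trail_W": peaks.P_max_trail.tolist(),
                "P_min_lead_W": peaks.P_min_lead.tolist(),
                "mean_P_max_trail_W": peaks.mean_trail,
                "mean_P_min_lead_W": peaks.mean_lead,
            }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written["summary"] = "summary.json"
    summary["files"] = written
    return summary
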