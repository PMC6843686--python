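"""End-to-end orchestration: simulate -> analyse -> report.

A pipeline run takes one configuration (preset name, replica seeds,
frame count, stage list, stage parameters), executes the requested
stages in dependency order for every replica, aggregates a report, and
emits a reproducibility manifest (config hash, seeds, per-stage
parameters, output digests).  Replicas are enumerated by seed — the
study design this mirrors ran three independent simulations per
condition — and the report carries per-replica values plus pooled
summaries such as the rotation range across replicas.

All numbers in the report come from the standalone module functions
with the same parameters; there are no pipeline-only code paths.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bridges import bridge_state_series
from .errors import ConfigurationError
from .gates import (DEFAULT_OPEN_THRESHOLD, asymmetry_index, detect_modes,
                    gate_series, open_probability)
from .kinematics import twist_series
from .msm import ck_test, cluster_states, estimate_msm
from .synthetic import generate_trajectory, make_preset

ALL_STAGES = ("gates", "twist", "bridges", "msm")

DEFAULT_PARAMS = {
    "gate": "TTTT",
    "threshold": DEFAULT_OPEN_THRESHOLD,
    "bandwidth": 0.5,
    "block": "ATD+LBD",
    "reference_frame": 0,
    "bridge_mode": "CA-proxy",
    "bridge_pair": "AB",
    "n_states": 6,
    "lag_ns": 0.1,
    "ck_ks": [2, 3],
}


def _canonical_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _run_replica(seed: int, config: dict, params: dict, outdir: Path) -> dict:
    preset = config["preset"]
    spec, base, topology = make_preset(
        preset, seed=seed, n_frames=config.get("frames"),
        twist_endpoint_deg=config.get("twist_endpoint_deg"))
    traj, truth = generate_trajectory(spec, base, topology)
    result: dict = {"seed": seed, "n_frames": traj.n_frames}
    stages = config.get("stages", list(ALL_STAGES))

    if "gates" in stages:
        series = gate_series(traj, topology, params["gate"])
        modes = detect_modes(series.d_glun1, bandwidth=params["bandwidth"])
        result["gates"] = {
            "modes_A": [round(float(m), 3) for m in modes.modes],
            "mode_weights": [round(float(w), 4) for w in modes.weights],
            "open_probability": open_probability(series, params["threshold"]),
            "mean_asymmetry_A": float(np.mean(asymmetry_index(series))),
        }
        frame = pd.DataFrame({
            "frame": np.arange(traj.n_frames),
            "time_ps": series.times_ps,
            "d_GluN1": series.d_glun1,
            "d_GluN2B": series.d_glun2b,
            "asymmetry": asymmetry_index(series),
            "open_flag": (series.d_glun1 > params["threshold"])
                         & (series.d_glun2b > params["threshold"]),
        })
        frame.to_csv(outdir / f"gates_seed{seed}.csv", index=False)

    if "twist" in stages:
        tw = twist_series(traj, topology, block=params["block"],
                          reference_frame=params["reference_frame"])
        result["twist"] = {
            "final_deg": float(tw.twist_deg[-1]),
            "max_deg": float(np.max(np.abs(tw.twist_deg))),
            "final_lift_deg": float(tw.lift_deg[-1]),
        }
        pd.DataFrame({
            "frame": np.arange(traj.n_frames),
            "time_ps": tw.times_ps,
            "twist_deg": tw.twist_deg,
            "lift_deg": tw.lift_deg,
            "rmsd_align": tw.rmsd_align_A,
        }).to_csv(outdir / f"twist_seed{seed}.csv", index=False)

    if "bridges" in stages:
        state = bridge_state_series(traj, topology,
                                    pair=params["bridge_pair"],
                                    mode=params["bridge_mode"])
        result["bridges"] = {
            "fractions": state.fractions(),
            "n_transitions": int(len(state.transitions)),
        }
        pd.DataFrame({
            "frame": np.arange(traj.n_frames),
            "pair_id": params["bridge_pair"],
            "d_RD": state.d_rd,
            "d_RE": state.d_re,
            "label": state.labels,
        }).to_csv(outdir / f"bridges_seed{seed}.csv", index=False)

    if "msm" in stages:
        clusters = cluster_states(traj, n_states=params["n_states"], seed=seed)
        model = estimate_msm(clusters.labels, traj.frame_interval_ps,
                             lag_ns=params["lag_ns"])
        ck = ck_test(model, ks=params["ck_ks"])
        result["msm"] = {
            "stationary": [round(float(p), 4)
                           for p in model.stationary_distribution],
            "implied_timescales_ns": [round(float(t), 4)
                                      for t in model.implied_timescales_ns[:5]],
            "ck_max_deviation": {str(k): round(v, 4)
                                 for k, v in ck.max_deviation.items()},
            "ck_passed": ck.all_passed,
        }
        with open(outdir / f"msm_seed{seed}.json", "w") as fh:
            json.dump({
                "transition_matrix": model.transition_matrix.tolist(),
                "count_matrix": model.count_matrix.tolist(),
                "stationary": model.stationary_distribution.tolist(),
                "implied_timescales_ns": model.implied_timescales_ns.tolist(),
                "net_flux": model.net_flux_matrix.tolist(),
            }, fh, indent=1)

    if "twist" in stages and "twist_deg" in truth:
        result["twist"]["programmed_final_deg"] = float(truth["twist_deg"][-1])
    return result


def run_pipeline(config: dict, outdir) -> tuple[dict, dict]:
    """Execute a configured multi-replica run; returns (manifest, report).

    ``config`` keys: ``preset`` (required), ``seeds`` (list, default
    [1]), ``frames``, ``stages`` (subset of gates/twist/bridges/msm;
    empty list = manifest only), ``twist_endpoint_deg``, ``params``
    (stage parameter overrides).  A stage failure aborts with the
    failing stage named; outputs written before the failure remain.
    """
    if "preset" not in config:
        raise ConfigurationError("config must name a preset")
    unknown = set(config) - {"preset", "seeds", "frames", "stages",
                             "twist_endpoint_deg", "params"}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", list(ALL_STAGES))
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ConfigurationError(f"unknown stages: {sorted(bad)}")

    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    seeds = list(config.get("seeds", [1]))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    replicas = []
    for seed in seeds:
        try:
            replicas.append(_run_replica(seed, config, params, outdir))
        except Exception as exc:
            raise ConfigurationError(
                f"pipeline stage failed for seed {seed}: {exc}") from exc

    report = {"preset": config["preset"], "replicas": replicas}
    if stages and "twist" in stages:
        finals = [r["twist"]["final_deg"] for r in replicas]
        report["twist_summary"] = {
            "min_final_deg": min(finals),
            "max_final_deg": max(finals),
            "range_deg": [min(finals), max(finals)],
        }
    if stages and "gates" in stages:
        report["open_probability_by_replica"] = [
            r["gates"]["open_probability"] for r in replicas]

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1)

    outputs = sorted(p for p in outdir.iterdir() if p.is_file())
    manifest = {
        "tool_version": __version__,
        "config": config,
        "config_hash": _canonical_hash(config),
        "seeds": seeds,
        "parameters": params,
        "outputs": {p.name: _file_digest(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest, report
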