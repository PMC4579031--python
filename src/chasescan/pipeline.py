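"""End-to-end orchestration: simulate -> gaze -> events -> templates.

A single YAML/dict config drives the full pipeline deterministically; all
randomness flows from the master seed through named substreams.  Outputs
are plain-text trajectories, gaze recordings, event files, template
containers and a JSON metrics manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from chasescan import fileio
from chasescan.behavior import fit_bernoulli, fit_lognormal
from chasescan.events_basic import segment_basic
from chasescan.events_complex import extract_complex, label_saccades
from chasescan.ideal import io_analysis, io_samples
from chasescan.preproc import preprocess
from chasescan.stimulus import StimulusParams, generate_batch
from chasescan.synthgaze import ObserverParams, detect_press, simulate_observer
from chasescan.templates import (Lock, SampleSpec, extract_samples,
                                 pca_templates, rail_diagram, fit_lines)

__all__ = ["run_pipeline", "default_config", "substream", "detection_locks"]


def default_config() -> dict:
    return {
        "seed": 1,
        "n_trials": 8,
        "condition": "mixed",
        "observers": [
            {"name": "obs_group", "strategy": "group"},
            {"name": "obs_single", "strategy": "single_agent"},
        ],
        "noise_sd": 0.1,
        "io_samples": 500,
        "stimulus": {},
    }


def substream(master_seed: int, name: str) -> int:
    """Deterministic named substream seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def detection_locks(gazes, trials, fused, spec: SampleSpec) -> list[Lock]:
    """Detection-event locks: fused gaze at (button press - 200 ms)."""
    locks = []
    for gaze, traj, fg in zip(gazes, trials, fused):
        press, correct = detect_press(gaze, traj)
        if press is None or not correct:
            continue
        frame = int(round((press - 0.2) * traj.frame_rate))
        if not 0 <= frame < traj.n_frames:
            continue
        pos = fg.xy[frame]
        if not np.all(np.isfinite(pos)):
            continue
        vel = fg.velocity_vec[frame]
        gaze_dir = None
        if np.all(np.isfinite(vel)) and np.hypot(*vel) > 4.0:
            gaze_dir = float(np.degrees(np.arctan2(vel[1], vel[0])))
        locks.append(Lock(traj=traj, frame=frame, pos=np.asarray(pos),
                          gaze_dir=gaze_dir))
    return locks


DETECTION_SPEC = SampleSpec(lock_kind="detection", t_lo=-0.8, t_hi=0.0,
                            rotation_source="gaze_direction")


def run_pipeline(config, out_dir) -> dict:
    """Run the full pipeline; returns the metrics manifest."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**default_config(), **(config or {})}
    out = Path(out_dir)
    (out / "trajectories").mkdir(parents=True, exist_ok=True)
    (out / "gaze").mkdir(exist_ok=True)
    (out / "events").mkdir(exist_ok=True)
    (out / "templates").mkdir(exist_ok=True)
    seed = int(cfg["seed"])

    params = StimulusParams(**cfg.get("stimulus", {}))
    trials = generate_batch(params, int(cfg["n_trials"]), cfg["condition"],
                            substream(seed, "stimulus"))
    for k, tr in enumerate(trials):
        fileio.write_trajectory(tr, out / "trajectories" / f"trial{k:03d}.txt")

    manifest = {"seed": seed, "n_trials": len(trials),
                "conditions": [t.condition for t in trials], "observers": {}}

    for obs_cfg in cfg["observers"]:
        name = obs_cfg["name"]
        op = ObserverParams(strategy=obs_cfg["strategy"],
                            noise_sd=float(cfg["noise_sd"]))
        gazes, fused, presses, n_events = [], [], [], 0
        for k, tr in enumerate(trials):
            lg = simulate_observer(tr, op, substream(seed, f"{name}:gaze{k}"))
            fg = preprocess(lg.time, lg.left_xy, lg.right_xy, tr.n_frames)
            evs = segment_basic(fg, tr)
            cx = extract_complex(evs)
            label_saccades(evs, cx)
            fileio.write_gaze(lg, out / "gaze" / f"{name}_trial{k:03d}.asc",
                              out / "events" / f"{name}_trial{k:03d}_truth.txt")
            fileio.write_events(evs, out / "events" / f"{name}_trial{k:03d}.txt")
            gazes.append(lg)
            fused.append(fg)
            presses.append(detect_press(lg, tr))
            n_events += len(evs)

        times = [p for p, ok in presses if p is not None and ok]
        correct = [ok for _, ok in presses]
        obs_manifest = {"n_events": n_events,
                        "n_detections": len(times),
                        "detection_rate": fit_bernoulli(
                            correct, seed=substream(seed, f"{name}:boot"))["rate"]}
        if len(times) >= 2:
            obs_manifest["mean_detection_time"] = fit_lognormal(
                times, seed=substream(seed, f"{name}:boot2")).mean_time
        locks = detection_locks(gazes, trials, fused, DETECTION_SPEC)
        if len(locks) >= 2:
            d_samples = extract_samples(locks, DETECTION_SPEC)
            if len(d_samples) >= 2:
                pca = pca_templates(d_samples, k=min(5, len(d_samples)))
                fileio.write_template(
                    pca.movies[0], out / "templates" / f"{name}_detection_pc1",
                    {"kind": "detection_pc1", "n_samples": len(d_samples),
                     "var_percent": (100 * pca.var_frac).tolist()})
                obs_manifest["detection_pc1_var_percent"] = \
                    float(100 * pca.var_frac[0])
        manifest["observers"][name] = obs_manifest

    n_io = int(cfg["io_samples"])
    if n_io > 0:
        samples = io_samples(trials, n=n_io, seed=substream(seed, "io"))
        res = io_analysis(samples)
        fileio.write_template(res["pca"].movies[0], out / "templates" / "io_pc1",
                              {"kind": "io_pc1", "n_samples": len(samples),
                               "var_percent": res["var_percent"]})
        manifest["ideal_observer"] = {
            "pc1_var_percent": res["pc1_var_percent"],
            "var_percent": res["var_percent"],
            "ridge_speeds": list(res["ridge_speeds"]),
            "line_offset_difference": res["line_offset_difference"],
            "inter_ridge_distance_at_lock": res["inter_ridge_distance_at_lock"],
        }

    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
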