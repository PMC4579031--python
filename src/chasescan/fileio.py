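"""Plain-text file formats for trajectories, gaze recordings and events.

Trajectory files carry a key=value header block followed by one line per
frame; gaze files use an ASC-like dialect with one line per 2 ms sample
and "." for missing coordinates; event files have one line per event.
An .npz container mirrors the trajectory format for speed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from chasescan.events_basic import BasicEvent
from chasescan.stimulus import StimulusParams, TrialTrajectory
from chasescan.synthgaze import LabeledGaze

__all__ = ["write_trajectory", "read_trajectory", "write_trajectory_npz",
           "read_trajectory_npz", "write_gaze", "read_gaze", "write_events",
           "read_events", "write_template"]

_PARAM_FIELDS = ("n_agents", "ring_diameter", "speed", "dir_change_rate",
                 "turn_range", "arena_side", "min_chase_dist", "frame_rate",
                 "trial_duration", "nc_fraction")


def write_trajectory(traj: TrialTrajectory, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# chaser={traj.chaser_idx} chasee={traj.chasee_idx} "
                 f"condition={traj.condition} frame_rate={traj.frame_rate}\n")
        if traj.params is not None:
            kv = " ".join(f"{k}={getattr(traj.params, k)}" for k in _PARAM_FIELDS)
            fh.write(f"# params {kv}\n")
        n, f = traj.n_agents, traj.n_frames
        fh.write(f"# n_agents={n} n_frames={f}\n")
        for t in range(f):
            row = traj.positions[:, t, :].ravel()
            fh.write(str(t) + " " + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_trajectory(path) -> TrialTrajectory:
    path = Path(path)
    meta, params, rows = {}, None, []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("params"):
                    kv = dict(p.split("=") for p in body.split()[1:])
                    params = StimulusParams(
                        n_agents=int(kv["n_agents"]),
                        ring_diameter=float(kv["ring_diameter"]),
                        speed=float(kv["speed"]),
                        dir_change_rate=float(kv["dir_change_rate"]),
                        turn_range=float(kv["turn_range"]),
                        arena_side=float(kv["arena_side"]),
                        min_chase_dist=float(kv["min_chase_dist"]),
                        frame_rate=float(kv["frame_rate"]),
                        trial_duration=float(kv["trial_duration"]),
                        nc_fraction=float(kv["nc_fraction"]))
                else:
                    meta.update(p.split("=") for p in body.split() if "=" in p)
            else:
                rows.append([float(v) for v in line.split()[1:]])
    arr = np.asarray(rows)
    n = int(meta["n_agents"])
    positions = arr.reshape(len(rows), n, 2).transpose(1, 0, 2)
    return TrialTrajectory(positions=positions, chaser_idx=int(meta["chaser"]),
                           chasee_idx=int(meta["chasee"]),
                           condition=meta["condition"],
                           frame_rate=float(meta["frame_rate"]), params=params)


def write_trajectory_npz(traj: TrialTrajectory, path) -> None:
    np.savez_compressed(path, positions=traj.positions,
                        chaser=traj.chaser_idx, chasee=traj.chasee_idx,
                        condition=traj.condition, frame_rate=traj.frame_rate)


def read_trajectory_npz(path) -> TrialTrajectory:
    z = np.load(path, allow_pickle=False)
    return TrialTrajectory(positions=z["positions"],
                           chaser_idx=int(z["chaser"]), chasee_idx=int(z["chasee"]),
                           condition=str(z["condition"]),
                           frame_rate=float(z["frame_rate"]))


def _fmt(v: float) -> str:
    return "." if not np.isfinite(v) else f"{v:.4f}"


def write_gaze(gaze: LabeledGaze, path, events_path=None) -> None:
    """ASC-like raw gaze file plus an optional truth-event sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# time_ms lx ly rx ry ('.' = missing)\n")
        for i in range(len(gaze.time)):
            t_ms = gaze.time[i] * 1000.0
            l, r = gaze.left_xy[i], gaze.right_xy[i]
            fh.write(f"{t_ms:.1f} {_fmt(l[0])} {_fmt(l[1])} "
                     f"{_fmt(r[0])} {_fmt(r[1])}\n")
    if events_path is not None:
        write_events(gaze.truth_events, events_path)


def read_gaze(path):
    """Returns (time_s, left_xy, right_xy) arrays from an ASC-like file."""
    t, left, right = [], [], []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            t.append(float(parts[0]) / 1000.0)
            vals = [np.nan if p == "." else float(p) for p in parts[1:5]]
            left.append(vals[0:2])
            right.append(vals[2:4])
    return np.asarray(t), np.asarray(left), np.asarray(right)


def write_events(events: list[BasicEvent], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# kind t_start_ms t_end_ms agents\n")
        for e in events:
            agents = ",".join(str(a) for a in sorted(e.focused_agents))
            fh.write(f"{e.kind} {e.t_start * 1000:.1f} {e.t_end * 1000:.1f} "
                     f"{agents or '-'}\n")


def read_events(path, frame_rate: float = 85.0) -> list[BasicEvent]:
    events = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            kind, t0, t1, agents = line.split()
            t0, t1 = float(t0) / 1000.0, float(t1) / 1000.0
            ag = frozenset() if agents == "-" else \
                frozenset(int(a) for a in agents.split(","))
            events.append(BasicEvent(kind, int(round(t0 * frame_rate)),
                                     int(round(t1 * frame_rate)), t0, t1, ag))
    return events


def write_template(movie_pixels: np.ndarray, path_base, meta: dict) -> None:
    """Template container: .npy array plus a JSON sidecar of its spec."""
    base = Path(path_base)
    np.save(base.with_suffix(".npy"), movie_pixels)
    with base.with_suffix(".json").open("w") as fh:
        json.dump(meta, fh, indent=1)
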