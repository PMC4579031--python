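"""Segmentation of fused gaze into basic oculomotor events.

Four basic events are extracted from gaze velocity, acceleration and
minimum duration: fixations, saccades, slow smooth movement (SSM) and
fast smooth movement (FSM).  The velocity/acceleration/duration bands:

    fixation  velocity [0, 6] deg/s   acceleration < 800    duration > 80 ms
    SSM       velocity [4, 21]        acceleration < 800    duration > 80 ms
    FSM       velocity [9, 21]        acceleration < 800    duration > 100 ms
    saccade   velocity > 21           acceleration > 4000   duration > 20 ms

Band membership is judged on run statistics rather than frame-wise: the
run's median velocity must lie in the band (so the oscillations of smooth
eye movement are not flagged as saccades), the <800 acceleration bounds on
the 95th percentile, and the saccade acceleration minimum on the run peak.
FSM additionally requires at least one agent that the gaze demonstrably
follows: mean gaze-agent distance < 1 deg during the first 100 ms, < 4 deg
over the whole event, and a median absolute gaze/agent direction
difference < 25 deg.  An SSM is any smooth event that does not qualify as
FSM (group tracking at reduced gain typically lands here); fixations and
SSMs focus all agents within 4 deg of the gaze on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chasescan.preproc import FusedGaze, _runs

__all__ = ["EventThresholds", "BasicEvent", "segment_basic",
           "fsm_agent_check", "focus_set_slow"]


@dataclass(frozen=True)
class EventThresholds:
    fixation_vel: tuple = (0.0, 6.0)
    fixation_acc: float = 800.0
    fixation_dur_ms: float = 80.0
    ssm_vel: tuple = (4.0, 21.0)
    ssm_acc: float = 800.0
    ssm_dur_ms: float = 80.0
    fsm_vel: tuple = (9.0, 21.0)
    fsm_acc: float = 800.0
    fsm_dur_ms: float = 100.0
    saccade_vel: float = 21.0
    saccade_acc: float = 4000.0
    saccade_dur_ms: float = 20.0
    # FSM focused-agent criteria
    fsm_onset_dist: float = 1.0      # mean gaze-agent distance, first 100 ms
    fsm_onset_ms: float = 100.0
    fsm_mean_dist: float = 4.0       # mean gaze-agent distance, whole event
    fsm_dir_diff: float = 25.0       # median |gaze-agent direction difference|
    focus_dist: float = 4.0          # fixation/SSM focused-agent distance
    # fraction of frames allowed outside the band within a run
    band_tolerance: float = 0.10


@dataclass(frozen=True)
class BasicEvent:
    kind: str                 # fixation | saccade | SSM | FSM
    start: int                # frame index, inclusive
    end: int                  # frame index, exclusive
    t_start: float
    t_end: float
    focused_agents: frozenset = field(default_factory=frozenset)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _agent_distances(gaze: FusedGaze, traj, start: int, end: int) -> np.ndarray:
    """(n_agents, n_frames) gaze-agent distances over [start, end)."""
    g = gaze.xy[start:end]
    pos = traj.positions[:, start:end, :]
    return np.hypot(pos[..., 0] - g[:, 0], pos[..., 1] - g[:, 1])


def fsm_agent_check(interval, gaze: FusedGaze, traj,
                    thresholds: EventThresholds = EventThresholds()) -> set:
    """Agents qualifying a smooth-movement interval as fast smooth movement.

    Evaluates, per agent, the three pursuit criteria (onset proximity,
    whole-event proximity, direction agreement); the interval qualifies
    as FSM iff the returned set is nonempty.
    """
    start, end = interval
    th = thresholds
    dist = _agent_distances(gaze, traj, start, end)
    n_onset = max(1, int(np.ceil(th.fsm_onset_ms / 1000.0 * gaze.frame_rate)))
    valid = ~gaze.missing_mask[start:end]
    gv = gaze.velocity_vec[start:end]
    gaze_dir = np.degrees(np.arctan2(gv[:, 1], gv[:, 0]))
    av = np.diff(traj.positions[:, max(start - 1, 0):end, :], axis=1)
    if av.shape[1] < end - start:  # pad first frame
        av = np.concatenate([av[:, :1], av], axis=1)
    agent_dir = np.degrees(np.arctan2(av[..., 1], av[..., 0]))
    out = set()
    for a in range(traj.n_agents):
        d = dist[a][valid]
        d_on = dist[a][:n_onset][valid[:n_onset]]
        if d.size == 0 or d_on.size == 0:
            continue
        if d_on.mean() >= th.fsm_onset_dist or d.mean() >= th.fsm_mean_dist:
            continue
        diff = np.abs((gaze_dir - agent_dir[a] + 180.0) % 360.0 - 180.0)[valid]
        if np.median(diff) < th.fsm_dir_diff:
            out.add(a)
    return out


def focus_set_slow(interval, gaze: FusedGaze, traj,
                   thresholds: EventThresholds = EventThresholds()) -> set:
    """Agents focused during a fixation or SSM: mean distance < 4 deg."""
    start, end = interval
    valid = ~gaze.missing_mask[start:end]
    if not valid.any():
        return set()
    dist = _agent_distances(gaze, traj, start, end)[:, valid]
    return set(np.flatnonzero(dist.mean(axis=1) < thresholds.focus_dist).tolist())


def _coarse_labels(gaze: FusedGaze, th: EventThresholds) -> np.ndarray:
    """Per-frame coarse class: 0 missing, 1 low, 2 smooth, 3 fast."""
    v = gaze.velocity
    lab = np.zeros(len(v), dtype=np.int8)
    ok = np.isfinite(v) & ~gaze.missing_mask
    lab[ok & (v <= th.fixation_vel[1])] = 1
    lab[ok & (v > th.fixation_vel[1]) & (v <= th.ssm_vel[1])] = 2
    lab[ok & (v > th.saccade_vel)] = 3
    return lab


def _refine_saccade_bounds(lab: np.ndarray, velocity: np.ndarray,
                           peak_frac: float = 0.70) -> np.ndarray:
    """Trim fast runs to frames above ``peak_frac`` of the run's peak velocity.

    The 20-ms position smoothing widens the super-threshold velocity bump
    of a saccade well beyond its true extent; keeping the contiguous core
    above ~55% of peak restores near-physical onset/offset.  Trimmed
    flank frames inherit the class of the adjacent run so they rejoin the
    neighboring smooth event.
    """
    lab = lab.copy()
    for lo, hi in _runs(lab == 3):
        v = velocity[lo:hi]
        if not np.isfinite(v).any():
            continue
        pk = int(np.nanargmax(v))
        thr = peak_frac * v[pk]
        a = pk
        while a > 0 and np.isfinite(v[a - 1]) and v[a - 1] >= thr:
            a -= 1
        b = pk
        while b < len(v) - 1 and np.isfinite(v[b + 1]) and v[b + 1] >= thr:
            b += 1
        lab[lo:lo + a] = 4       # transition flanks: glue, no statistics
        lab[lo + b + 1:hi] = 4
    return lab


def _merge_flickers(lab: np.ndarray, max_len: int = 2) -> np.ndarray:
    """Absorb runs of <= max_len frames whose neighbors agree on a class."""
    lab = lab.copy()
    for _ in range(4):
        changed = False
        runs = []
        s = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[s]:
                runs.append((s, i, lab[s]))
                s = i
        for k in range(1, len(runs) - 1):
            s, e, c = runs[k]
            lc, rc = runs[k - 1][2], runs[k + 1][2]
            # fast (saccadic) runs of >=2 frames clear the 20 ms duration
            # minimum and are kept even when embedded in a smooth stretch
            limit = 1 if c == 3 else max_len
            if (e - s) <= limit and lc == rc and lc != c and lc != 0:
                lab[s:e] = lc
                changed = True
        if not changed:
            break
    return lab


def segment_basic(gaze: FusedGaze, traj=None,
                  thresholds: EventThresholds = EventThresholds()) -> list[BasicEvent]:
    """Segment fused gaze into basic events.

    Saccades are extracted first (velocity above 21 deg/s for more than
    20 ms with peak acceleration above 4000 deg/s^2); the remaining runs
    are tested FSM -> SSM -> fixation, in that precedence order, since the
    SSM band contains the FSM band and overlaps the fixation band.  Frames
    failing every test are left unlabeled.  Missing frames break runs.
    When ``traj`` is None the FSM agent criteria cannot be evaluated and
    smooth runs fall through to SSM.
    """
    th = thresholds
    if np.all(gaze.missing_mask):
        return []
    lab = _merge_flickers(_coarse_labels(gaze, th))
    lab = _refine_saccade_bounds(lab, gaze.velocity)
    fr = gaze.frame_rate
    acc_q = 100.0 * (1.0 - th.band_tolerance)

    def collect_runs():
        out = []
        s = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[s]:
                out.append([s, i, int(lab[s])])
                s = i
        return out

    # short velocity-ramp fragments bracketing a saccade (the smoothed
    # rise through the 6-21 deg/s band) are transition glue as well
    runs = collect_runs()
    for k, (s, e, c) in enumerate(runs):
        if c in (1, 2) and (e - s) <= 3:
            near_sacc = ((k > 0 and runs[k - 1][2] in (3, 4)) or
                         (k + 1 < len(runs) and runs[k + 1][2] in (3, 4)))
            if near_sacc:
                lab[s:e] = 4
    runs = collect_runs()

    # Transition glue attaches to the extent of the nearest non-saccade
    # run on the side away from the saccade, mirroring how a coder marks
    # event boundaries on smoothed data.  Statistics below are computed
    # on the core run, duration on the extended extent.
    ext = [[s, e] for s, e, _ in runs]
    for k, (s, e, c) in enumerate(runs):
        if c != 4:
            continue
        left_ok = k > 0 and runs[k - 1][2] in (1, 2)
        right_ok = k + 1 < len(runs) and runs[k + 1][2] in (1, 2)
        if left_ok and (not right_ok or runs[k + 1][2] == 3):
            ext[k - 1][1] = e
        elif right_ok:
            ext[k + 1][0] = s

    events: list[BasicEvent] = []
    for k, (s, e, c) in enumerate(runs):
        s_x, e_x = ext[k]
        dur_ms = (e_x - s_x) / fr * 1000.0
        kind, agents = None, frozenset()
        if c == 3:
            acc_ch = gaze.acc_peak if gaze.acc_peak is not None else gaze.acceleration
            seg = acc_ch[s:e]
            peak = np.nanmax(seg) if np.isfinite(seg).any() else -np.inf
            if dur_ms > th.saccade_dur_ms and peak > th.saccade_acc:
                kind = "saccade"
        elif c in (1, 2):
            v = gaze.velocity[s:e]
            v = v[np.isfinite(v)]
            acc = gaze.acceleration[s:e]
            acc = acc[np.isfinite(acc)]
            acc_hi = np.percentile(acc, acc_q) if acc.size else np.inf
            med = np.median(v) if v.size else np.nan
            if (dur_ms > th.fsm_dur_ms and th.fsm_vel[0] <= med <= th.fsm_vel[1]
                    and acc_hi < th.fsm_acc and traj is not None):
                ag = fsm_agent_check((s, e), gaze, traj, th)
                if ag:
                    kind, agents = "FSM", frozenset(ag)
            if (kind is None and dur_ms > th.ssm_dur_ms
                    and th.ssm_vel[0] <= med <= th.ssm_vel[1]
                    and acc_hi < th.ssm_acc):
                kind = "SSM"
                agents = frozenset(focus_set_slow((s, e), gaze, traj, th)) \
                    if traj is not None else frozenset()
            if (kind is None and dur_ms > th.fixation_dur_ms
                    and med <= th.fixation_vel[1] and acc_hi < th.fixation_acc):
                kind = "fixation"
                agents = frozenset(focus_set_slow((s, e), gaze, traj, th)) \
                    if traj is not None else frozenset()
        if kind is not None:
            events.append(BasicEvent(kind, s_x, e_x, s_x / fr, e_x / fr, agents))
    return events
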