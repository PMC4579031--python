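import numpy as np
import pytest

from chasescan.events_basic import (EventThresholds, fsm_agent_check,
                                    focus_set_slow, segment_basic)
from chasescan.preproc import FusedGaze, derive_kinematics
from chasescan.stimulus import TrialTrajectory


def _gaze_from_xy(xy, frame_rate=85.0, acc_peak=None):
    speed, acc, vel = derive_kinematics(xy, frame_rate)
    return FusedGaze(time=np.arange(len(xy)) / frame_rate, xy=xy,
                     velocity=speed, acceleration=acc,
                     missing_mask=np.zeros(len(xy), bool), velocity_vec=vel,
                     acc_peak=acc_peak, frame_rate=frame_rate)


def _traj_from_paths(paths):
    """paths: list of (n_frames, 2) agent paths."""
    pos = np.stack(paths)  # (n_agents, n_frames, 2)
    return TrialTrajectory(positions=pos, chaser_idx=0, chasee_idx=1,
                           condition="DC", frame_rate=85.0)


class TestSegmentBasic:
    def test_pure_fixation_trace(self):
        xy = np.tile([1.0, 2.0], (200, 1))
        evs = segment_basic(_gaze_from_xy(xy))
        assert len(evs) == 1 and evs[0].kind == "fixation"
        assert evs[0].start == 0 and evs[0].end == 200

    def test_gaze_locked_to_agent_is_fsm(self):
        t = np.arange(200) / 85.0
        path = np.column_stack([14.5 * t - 15.0, np.zeros_like(t)])
        traj = _traj_from_paths([path, path + [0, 8.0]])
        evs = segment_basic(_gaze_from_xy(path.copy()), traj)
        assert len(evs) == 1 and evs[0].kind == "FSM"
        assert 0 in evs[0].focused_agents

    def test_entirely_missing_returns_empty(self):
        xy = np.full((100, 2), np.nan)
        g = _gaze_from_xy(xy)
        g.missing_mask[:] = True
        assert segment_basic(g) == []

    def test_minimum_durations_respected(self, dc_trial, fused_group_clean):
        th = EventThresholds()
        mins = {"fixation": th.fixation_dur_ms, "SSM": th.ssm_dur_ms,
                "FSM": th.fsm_dur_ms, "saccade": th.saccade_dur_ms}
        for e in segment_basic(fused_group_clean, dc_trial):
            assert e.duration * 1000 > mins[e.kind]

    def test_saccades_carry_no_agents(self, dc_trial, events_group_clean):
        for e in events_group_clean:
            if e.kind == "saccade":
                assert not e.focused_agents

    def test_truth_fsm_recovered(self, dc_trial, gaze_single_clean):
        """Zero-noise truth FSM intervals overlap recovered FSMs >= 80%."""
        from chasescan.preproc import preprocess
        g = gaze_single_clean
        fg = preprocess(g.time, g.left_xy, g.right_xy, dc_trial.n_frames)
        evs = segment_basic(fg, dc_trial)
        rec = np.zeros(dc_trial.n_frames, bool)
        for e in evs:
            if e.kind == "FSM":
                rec[e.start:e.end] = True
        overlaps = [rec[e.start:e.end].mean()
                    for e in g.truth_events
                    if e.kind == "FSM" and e.end - e.start >= 12]
        assert np.mean(overlaps) >= 0.8


class TestFsmAgentCheck:
    def _setup(self, offset=(0.0, 0.0), angle=0.0):
        t = np.arange(120) / 85.0
        gaze = np.column_stack([14.5 * t, np.zeros_like(t)])
        a = np.radians(angle)
        path = np.column_stack([14.5 * t * np.cos(a), 14.5 * t * np.sin(a)])
        path += np.asarray(offset)
        traj = _traj_from_paths([path, path + [0, 20.0]])
        return _gaze_from_xy(gaze), traj

    def test_identical_path_qualifies(self):
        gaze, traj = self._setup()
        assert 0 in fsm_agent_check((0, 120), gaze, traj)

    def test_orthogonal_direction_excluded(self):
        gaze, traj = self._setup(angle=90.0)
        assert 0 not in fsm_agent_check((0, 120), gaze, traj)

    def test_matches_bruteforce_criteria(self, dc_trial, fused_group_clean):
        th = EventThresholds()
        g, traj = fused_group_clean, dc_trial
        interval = (400, 460)
        got = fsm_agent_check(interval, g, traj, th)
        s, e = interval
        expect = set()
        for a in range(traj.n_agents):
            d = np.hypot(*(traj.positions[a, s:e].T - g.xy[s:e].T))
            onset = d[:int(np.ceil(0.1 * 85))]
            gd = np.degrees(np.arctan2(g.velocity_vec[s:e, 1],
                                       g.velocity_vec[s:e, 0]))
            ap = np.diff(traj.positions[a, s - 1:e], axis=0)
            ad = np.degrees(np.arctan2(ap[:, 1], ap[:, 0]))
            diff = np.abs((gd - ad + 180) % 360 - 180)
            if onset.mean() < 1 and d.mean() < 4 and np.median(diff) < 25:
                expect.add(a)
        assert got == expect


class TestFocusSetSlow:
    def test_distance_threshold(self):
        t = np.arange(100) / 85.0
        gaze = np.tile([0.0, 0.0], (100, 1))
        near = np.tile([2.0, 0.0], (100, 1))
        far = np.tile([5.0, 0.0], (100, 1))
        traj = _traj_from_paths([near, far])
        got = focus_set_slow((0, 100), _gaze_from_xy(gaze), traj)
        assert got == {0}

    def test_matches_mean_distance_oracle(self, dc_trial, fused_group_clean):
        interval = (100, 160)
        got = focus_set_slow(interval, fused_group_clean, dc_trial)
        s, e = interval
        expect = {a for a in range(dc_trial.n_agents)
                  if np.hypot(*(dc_trial.positions[a, s:e].T
                                - fused_group_clean.xy[s:e].T)).mean() < 4}
        assert got == expect
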