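import numpy as np
import pytest
from scipy import stats

from chasescan.stimulus import (StimulusParams, TrialTrajectory, chaser_heading,
                                generate_trial, nearest_neighbor_stats,
                                reflect_off_wall, step_direction)


class _FixedRng:
    """Stub returning a preset uniform draw."""

    def __init__(self, value):
        self.value = value

    def uniform(self, lo, hi):
        return self.value


class TestStepDirection:
    def test_zero_turn_identity(self):
        assert step_direction(0.0, _FixedRng(0.0)) == 0.0

    def test_wraparound(self):
        assert step_direction(350.0, _FixedRng(30.0)) == pytest.approx(20.0)

    def test_turns_uniform_on_pm60(self):
        rng = np.random.default_rng(0)
        draws = np.array([step_direction(0.0, rng) for _ in range(100_000)])
        turns = (draws + 180.0) % 360.0 - 180.0
        assert stats.kstest(turns, stats.uniform(-60, 120).cdf).pvalue > 0.01


class TestChaserHeading:
    @pytest.mark.parametrize("chaser,chasee,expected", [
        ((0, 0), (1, 0), 0.0),
        ((0, 0), (0, -1), 270.0),
        ((0, 0), (0, 1), 90.0),
    ])
    def test_examples(self, chaser, chasee, expected):
        assert chaser_heading(chaser, chasee) == pytest.approx(expected)

    def test_matches_atan2_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = rng.uniform(-10, 10, 2), rng.uniform(-10, 10, 2)
            if np.allclose(a, b):
                continue
            expect = np.degrees(np.arctan2(b[1] - a[1], b[0] - a[0])) % 360
            assert chaser_heading(a, b) == pytest.approx(expect)

    def test_coincident_raises(self):
        with pytest.raises(ValueError):
            chaser_heading((1, 1), (1, 1))


class TestReflect:
    def test_right_wall_mirrors(self):
        _, d, b = reflect_off_wall((13.5, 0.0), 30.0, 26.0)
        assert b and d == pytest.approx(150.0)

    def test_bottom_wall_mirrors(self):
        _, d, b = reflect_off_wall((0.0, -13.5), 270.0, 26.0)
        assert b and d == pytest.approx(90.0)

    def test_random_bounces_stay_inside(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            pos = rng.uniform(13.0, 15.0, 2) * rng.choice([-1, 1], 2)
            pos2, d, _ = reflect_off_wall(pos, rng.uniform(0, 360), 26.0)
            assert np.all(np.abs(pos2) <= 13.0)
            assert 0 <= d < 360


class TestGenerateTrial:
    def test_dc_min_distance(self, dc_trial):
        assert dc_trial.chase_distance().min() >= 3.0

    def test_constant_speed_off_bounce(self, dc_trial):
        disp = np.hypot(*np.diff(dc_trial.positions, axis=1).transpose(2, 0, 1))
        speed = disp * dc_trial.frame_rate
        mask = np.ones_like(speed, dtype=bool)
        for a, frames in enumerate(dc_trial.bounce_log):
            mask[a, frames - 1] = False
        assert np.abs(speed[mask] - 14.5).max() < 1e-9
        assert abs(speed.mean() - 14.5) < 0.15  # bounce folding shortens a few

    def test_containment(self, dc_trial, nc_trial):
        for tr in (dc_trial, nc_trial):
            assert np.abs(tr.positions).max() <= 13.0 + 1e-9

    def test_reproducible(self):
        p = StimulusParams(trial_duration=5.0)
        a = generate_trial(p, "DC", 7)
        b = generate_trial(p, "DC", 7)
        assert np.array_equal(a.positions, b.positions)

    def test_nc_trials_violate_min_distance(self):
        p = StimulusParams(trial_duration=10.0)
        mins = [generate_trial(p, "NC", s).chase_distance().min()
                for s in range(8)]
        assert min(mins) < 3.0

    def test_direction_change_rate(self):
        p = StimulusParams()
        rates = []
        for s in range(10):
            tr = generate_trial(p, "DC", 50 + s)
            rates.append(np.mean([len(c) for c in tr.dir_change_log])
                         / p.trial_duration)
        assert abs(np.mean(rates) - 5.4) < 0.25

    def test_heat_seeking_converges(self):
        # walls out of reach, chasee never turns: pure pursuit at equal
        # speed never increases the distance
        p = StimulusParams(arena_side=2000.0, dir_change_rate=1e-9,
                           trial_duration=5.0)
        tr = generate_trial(p, "NC", 3, chaser_continuous=True)
        assert np.all(np.diff(tr.chase_distance()) <= 1e-9)


class TestNearestNeighbor:
    def test_two_static_agents(self):
        pos = np.zeros((3, 10, 2))
        pos[1, :, 0] = 2.5
        pos[2, :, 0] = -4.0
        tr = TrialTrajectory(positions=pos, chaser_idx=0, chasee_idx=1,
                             condition="DC", frame_rate=85.0)
        out = nearest_neighbor_stats(tr)
        assert out["mean_chase_dist"] == pytest.approx(2.5)
        assert out["mean_distractor_nn_dist"] == pytest.approx(4.0)

    def test_matches_bruteforce(self, dc_trial):
        out = nearest_neighbor_stats(dc_trial)
        tr = dc_trial
        nn, cc = [], []
        distractors = [i for i in range(tr.n_agents)
                       if i not in (tr.chaser_idx, tr.chasee_idx)]
        for f in range(0, tr.n_frames, 17):
            pos = tr.positions[:, f, :]
            for i in distractors:
                d = [np.hypot(*(pos[i] - pos[j]))
                     for j in range(tr.n_agents) if j != i]
                nn.append(min(d))
            cc.append(np.hypot(*(pos[tr.chaser_idx] - pos[tr.chasee_idx])))
        assert out["mean_distractor_nn_dist"] == pytest.approx(
            np.mean(nn), rel=0.02)
        assert out["mean_chase_dist"] == pytest.approx(np.mean(cc), rel=0.02)

    def test_design_claim_rough_agreement(self):
        p = StimulusParams()
        nn, cc = [], []
        for s in range(10):
            out = nearest_neighbor_stats(generate_trial(p, "DC", 200 + s))
            nn.append(out["mean_distractor_nn_dist"])
            cc.append(out["mean_chase_dist"])
        rel = abs(np.mean(nn) - np.mean(cc)) / np.mean(cc)
        assert rel < 0.30
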