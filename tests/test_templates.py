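import numpy as np
import pytest

from chasescan.stimulus import TrialTrajectory
from chasescan.templates import (AlignedSample, Lock, RailDiagram, SampleSpec,
                                 _grid, _unimodal_pattern, dominant_direction,
                                 extract_samples, fit_lines, npr_template,
                                 pca_templates, rail_diagram, render_movie,
                                 render_sample)


def _linear_traj(dirs_deg, speed=14.5, n_frames=120, starts=None):
    """Straight-line agents; dirs in deg, optional start points."""
    t = np.arange(n_frames) / 85.0
    paths = []
    for k, d in enumerate(dirs_deg):
        s = np.zeros(2) if starts is None else np.asarray(starts[k], float)
        u = np.array([np.cos(np.radians(d)), np.sin(np.radians(d))])
        paths.append(s + speed * t[:, None] * u)
    return TrialTrajectory(positions=np.stack(paths), chaser_idx=0,
                           chasee_idx=min(1, len(dirs_deg) - 1),
                           condition="DC", frame_rate=85.0)


class TestDominantDirection:
    def test_single_agent_plus_x(self):
        tr = _linear_traj([0.0])
        assert dominant_direction(tr, (0, 60), np.zeros(2)) == pytest.approx(
            0.0, abs=1e-6)

    def test_distant_agent_has_zero_weight(self):
        tr = _linear_traj([0.0, 90.0], starts=[(0, 0), (6.0, 0)])
        # agent 1 starts 6 deg away and moves off: outside the 5-deg window
        assert dominant_direction(tr, (0, 20), np.zeros(2)) == pytest.approx(
            0.0, abs=1e-6)

    def test_no_agents_in_window_raises(self):
        tr = _linear_traj([0.0], starts=[(30.0, 30.0)])
        with pytest.raises(ValueError):
            dominant_direction(tr, (0, 20), np.zeros(2))

    def test_matches_weighted_histogram_oracle(self, dc_trial):
        lock = np.array([1.0, -2.0])
        got = dominant_direction(dc_trial, (300, 368), lock)
        pos = dc_trial.positions[:, 300:368, :]
        d = np.diff(pos, axis=1)
        dirs = np.degrees(np.arctan2(d[..., 1], d[..., 0])) % 360
        dist = np.hypot(pos[:, :-1, 0] - lock[0], pos[:, :-1, 1] - lock[1])
        w = np.maximum(0, 1 - (dist / 5.0) ** 2)
        hist = np.zeros(36)
        for a in range(dirs.shape[0]):
            for f in range(dirs.shape[1]):
                hist[int(dirs[a, f] // 10) % 36] += w[a, f]
        mode = np.argmax(hist)
        sel = (dirs // 10).astype(int) % 36 == mode
        ang = np.radians(dirs[sel])
        mean = np.degrees(np.arctan2((w[sel] * np.sin(ang)).sum(),
                                     (w[sel] * np.cos(ang)).sum())) % 360
        assert got == pytest.approx(mean, abs=1e-9)


class TestExtractSamples:
    def test_on_axis_agent_moves_at_speed(self):
        tr = _linear_traj([0.0])
        spec = SampleSpec(t_lo=-0.4, t_hi=0.4)
        lock = Lock(traj=tr, frame=60, pos=tr.positions[0, 60].copy())
        (s,) = extract_samples([lock], spec)
        x = s.coords[:, 0, 0]
        good = np.isfinite(x)
        slope = np.polyfit(s.t_rel[good], x[good], 1)[0]
        assert slope == pytest.approx(14.5, abs=0.01)
        assert np.allclose(s.coords[good, 0, 1], 0.0, atol=1e-9)

    def test_io_midpoint_lock_symmetric(self):
        # two agents running parallel 3.4 deg apart: midpoint lock puts
        # them at +/-1.7 on the alignment axis
        tr = _linear_traj([0.0, 0.0], starts=[(0, 0), (-3.4, 0)])
        spec = SampleSpec(t_lo=-0.4, t_hi=0.4)
        mid = 0.5 * (tr.positions[0, 60] + tr.positions[1, 60])
        (s,) = extract_samples([Lock(traj=tr, frame=60, pos=mid)], spec)
        k = np.argmin(np.abs(s.t_rel))
        assert s.coords[k, 0, 0] == pytest.approx(1.7, abs=0.15)
        assert s.coords[k, 1, 0] == pytest.approx(-1.7, abs=0.15)

    def test_rotation_is_isometry(self, dc_trial):
        spec = SampleSpec(t_lo=-0.2, t_hi=0.2)
        lock = Lock(traj=dc_trial, frame=500,
                    pos=dc_trial.positions[0, 500].copy())
        (s,) = extract_samples([lock], spec, crop_margin=100.0)
        rel = dc_trial.positions[:, 500 + np.arange(-17, 17), :] \
            - dc_trial.positions[0, 500]
        orig = np.transpose(rel, (1, 0, 2))
        d0 = np.linalg.norm(orig[:, :, None, :] - orig[:, None, :, :], axis=-1)
        d1 = np.linalg.norm(s.coords[:, :, None, :] - s.coords[:, None, :, :],
                            axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_rotating_the_world_leaves_samples_unchanged(self, dc_trial):
        # a bin-multiple rotation (histogram bins are 10 deg) keeps the
        # dominant-direction estimate exactly equivariant; generic angles
        # are equivariant only up to the binning resolution
        spec = SampleSpec(t_lo=-0.2, t_hi=0.2)
        a = np.radians(40.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        rot = TrialTrajectory(
            positions=dc_trial.positions @ R.T, chaser_idx=0, chasee_idx=1,
            condition="DC", frame_rate=85.0)
        for frame in (300, 900, 1500):
            l0 = Lock(traj=dc_trial, frame=frame,
                      pos=dc_trial.positions[0, frame].copy())
            l1 = Lock(traj=rot, frame=frame, pos=rot.positions[0, frame].copy())
            (s0,) = extract_samples([l0], spec)
            (s1,) = extract_samples([l1], spec)
            assert np.allclose(np.nan_to_num(s0.coords),
                               np.nan_to_num(s1.coords), atol=1e-6)

    def test_window_outside_trial_dropped(self):
        tr = _linear_traj([0.0])
        spec = SampleSpec(t_lo=-0.4, t_hi=0.4)
        out = extract_samples([Lock(traj=tr, frame=2, pos=np.zeros(2))], spec)
        assert out == []


def _random_samples(n, n_frames=5, n_agents=3, seed=0):
    rng = np.random.default_rng(seed)
    return [AlignedSample(coords=rng.uniform(-4, 4, (n_frames, n_agents, 2)),
                          t_rel=np.arange(n_frames) / 85.0, angle=0.0)
            for _ in range(n)]


class TestRendering:
    def test_single_stationary_agent_constant_blob(self):
        coords = np.tile([0.0, 0.0], (4, 1, 1)).reshape(4, 1, 2)
        s = AlignedSample(coords, np.arange(4) / 85.0, 0.0)
        mov = render_sample(s, 0.5, 4.0)
        assert np.allclose(mov[0], mov[1])
        i, j = np.unravel_index(np.argmax(mov[0]), mov[0].shape)
        ax = _grid(4.0, 0.5)
        assert abs(ax[i]) < 0.5 and abs(ax[j]) < 0.5

    def test_mirrored_samples_give_symmetric_template(self):
        a = AlignedSample(np.tile([2.0, 0.0], (3, 1, 1)).reshape(3, 1, 2),
                          np.arange(3) / 85.0, 0.0)
        b = AlignedSample(np.tile([-2.0, 0.0], (3, 1, 1)).reshape(3, 1, 2),
                          np.arange(3) / 85.0, 0.0)
        mov = render_movie([a, b], 0.25, 4.0)
        assert np.allclose(mov.pixels, mov.pixels[:, :, ::-1], atol=1e-6)

    def test_npr_equals_render_average(self):
        samples = _random_samples(10)
        m1 = render_movie(samples, 0.5, 4.0)
        m2 = npr_template(samples, 0.5, 4.0)
        assert np.abs(m1.pixels - m2.pixels).max() < 1e-6

    def test_variable_length_counts(self):
        samples = _random_samples(4, n_frames=6) + _random_samples(3, n_frames=3)
        mov = npr_template(samples, 0.5, 4.0)
        assert list(mov.counts) == [7, 7, 7, 4, 4, 4]


class TestPCA:
    def test_matches_dense_covariance_oracle(self):
        samples = _random_samples(20, n_frames=5)
        pca = pca_templates(samples, pixel_size=1.0, halfwidth=4.0, k=5,
                            center=True)
        X = np.stack([render_sample(s, 1.0, 4.0).ravel()
                      for s in samples]).astype(np.float64)
        Xc = X - X.mean(0)
        ev = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
        vf = ev[:5] / ev[ev > 1e-12].sum()
        assert np.abs(pca.var_frac - vf).max() < 1e-8

    def test_eigenmovies_orthonormal(self):
        pca = pca_templates(_random_samples(15), pixel_size=1.0, halfwidth=4.0,
                            k=5)
        M = pca.movies.reshape(5, -1).astype(np.float64)
        assert np.abs(M @ M.T - np.eye(5)).max() < 1e-6

    def test_identical_samples_degenerate(self):
        s = _random_samples(1)[0]
        clones = [AlignedSample(s.coords.copy(), s.t_rel, 0.0)
                  for _ in range(5)]
        pca = pca_templates(clones, pixel_size=1.0, halfwidth=4.0, k=3)
        assert pca.var_frac[0] > 0.999

    def test_pc1_recovers_mean_pc2_shift_dipole(self):
        # samples are one pattern +/- a small shift: the first component
        # is the pattern, the second a signed shift dipole
        base = np.tile([0.0, 0.0], (4, 1, 1)).reshape(4, 1, 2)
        samples = []
        for k in range(20):
            shift = 0.4 if k % 2 == 0 else -0.4
            samples.append(AlignedSample(base + [shift, 0.0],
                                         np.arange(4) / 85.0, 0.0))
        pca = pca_templates(samples, pixel_size=0.25, halfwidth=3.0, k=2)
        mean_mov = render_movie(samples, 0.25, 3.0).pixels
        c = np.corrcoef(pca.movies[0].ravel(), mean_mov.ravel())[0, 1]
        assert c > 0.99
        pc2 = pca.movies[1]
        assert pc2.min() < -0.01 and pc2.max() > 0.01  # signed dipole

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            pca_templates(_random_samples(1))


class TestRailDiagram:
    def test_equals_row_mean_oracle(self):
        samples = _random_samples(5)
        mov = render_movie(samples, 0.25, 4.0)
        rail = rail_diagram(mov)
        ax = mov.axis
        rows = np.flatnonzero(np.abs(ax) <= 0.15)
        assert np.allclose(rail.values, mov.pixels[:, rows, :].mean(axis=1))

    def test_constant_velocity_ridge_slope(self):
        T = 40
        tt = (np.arange(T) - 20) / 85.0
        coords = np.zeros((T, 1, 2))
        coords[:, 0, 0] = 14.5 * tt
        mov = render_movie([AlignedSample(coords, tt, 0.0)], 0.25, 5.0)
        rail = rail_diagram(mov)
        fit = fit_lines(rail, 1)
        assert fit.v == pytest.approx(14.5, abs=0.5)

    def test_two_agents_two_rails(self):
        T = 40
        tt = (np.arange(T) - 20) / 85.0
        coords = np.zeros((T, 2, 2))
        coords[:, 0, 0] = 14.5 * tt + 1.7
        coords[:, 1, 0] = 14.5 * tt - 1.7
        mov = render_movie([AlignedSample(coords, tt, 0.0)], 0.25, 5.0)
        rail = rail_diagram(mov)
        row = rail.values[20]
        peaks = [j for j in range(1, len(row) - 1)
                 if row[j] >= row[j - 1] and row[j] >= row[j + 1]
                 and row[j] > 0.5 * row.max()]
        assert len(peaks) == 2

    def test_band_without_rows_raises(self):
        mov = render_movie(_random_samples(2), 1.0, 4.0)
        with pytest.raises(ValueError):
            rail_diagram(mov, band=0.15)  # 1-deg pixels: no row center <=0.15


class TestFitLines:
    def test_flat_rail_raises(self):
        rail = RailDiagram(np.zeros((10, 20)), np.linspace(-5, 5, 20),
                           np.linspace(-0.4, 0.4, 10))
        with pytest.raises(ValueError):
            fit_lines(rail, 1)

    def test_inverse_crime_recovery(self):
        t = np.linspace(-0.4, 0.4, 68)
        x = _grid(5.0, 0.25)
        vals = _unimodal_pattern([(2.5, -13.5, 0.16)], t, x)
        fit = fit_lines(RailDiagram(vals, x, t), 1, normalize="global",
                        max_ridge_width=np.inf)
        assert abs(fit.p - 2.5) < 0.05
        assert abs(fit.v + 13.5) < 0.2

    def test_two_line_recovery(self):
        t = np.linspace(-0.4, 0.4, 68)
        x = _grid(5.0, 0.25)
        vals = _unimodal_pattern([(2.1, 13.9, 0.012), (-2.1, 14.1, 0.012)], t, x)
        fit = fit_lines(RailDiagram(vals, x, t), 2)
        (p1, v1, _), (p2, v2, _) = fit.lines
        assert p1 == pytest.approx(2.1, abs=0.05)
        assert p2 == pytest.approx(-2.1, abs=0.05)
        assert v1 == pytest.approx(13.9, abs=0.2)
        assert v2 == pytest.approx(14.1, abs=0.2)

    def test_simplex_beats_coarse_grid(self):
        t = np.linspace(-0.4, 0.4, 40)
        x = _grid(5.0, 0.5)
        rng = np.random.default_rng(3)
        vals = _unimodal_pattern([(1.2, -12.0, 0.01)], t, x) \
            + 0.05 * rng.normal(size=(40, 20))
        rail = RailDiagram(vals, x, t)
        fit = fit_lines(rail, 1, normalize="global", max_ridge_width=np.inf)
        norm = (vals - vals.min()) / (vals.max() - vals.min())

        def corr(p, v, s):
            pat = _unimodal_pattern([(p, v, s)], t, x)
            a = norm.ravel() - norm.mean()
            b = pat.ravel() - pat.mean()
            nb = np.linalg.norm(b)
            return 0.0 if nb == 0 else a @ b / (np.linalg.norm(a) * nb)

        best = -np.inf
        arg = None
        for p in np.linspace(-4, 4, 41):
            for v in np.linspace(-20, 20, 41):
                for s in np.linspace(0.005, 0.05, 11):
                    c = corr(p, v, s)
                    if c > best:
                        best, arg = c, (p, v, s)
        assert fit.correlation >= best - 1e-6
        assert abs(fit.p - arg[0]) <= 0.25
        assert abs(fit.v - arg[1]) <= 1.2
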