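"""Synthetic observer: labeled binocular gaze over a chasing display.

The observer alternates exploration (fixations plus relocating saccades
toward regions of high agent density) with pursuit (a catch-up saccade to
a nearby close pair of agents -- or one member of it -- followed by smooth
movement at a configurable gain of the target velocity with small
velocity oscillations, re-aligned by further catch-up saccades).  Two
strategies mirror the tracking styles observed in humans: ``group``
tracks the pair center with gain ~0.75; ``single_agent`` locks individual
agents with gain ~0.97.

Ground-truth event labels are derived from the construction itself: the
planned fixation/saccade/smooth segments are mapped to display frames and
smooth segments are labeled FSM or SSM by the same proximity/direction
criteria the segmenter uses, evaluated on the noiseless gaze path.  The
raw output adds per-eye white positional noise and blink gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chasescan.events_basic import BasicEvent, EventThresholds, fsm_agent_check, focus_set_slow
from chasescan.events_complex import ComplexEvent, extract_complex
from chasescan.preproc import FusedGaze, derive_kinematics
from chasescan.stimulus import TrialTrajectory

__all__ = ["ObserverParams", "LabeledGaze", "simulate_observer",
           "density_saccade_target", "detect_press"]


@dataclass(frozen=True)
class ObserverParams:
    strategy: str = "group"            # "group" | "single_agent"
    pursuit_gain: float | None = None  # None -> 0.75 group, 0.97 single
    fixation_dur_mean_ms: float = 400.0
    smooth_episode_dur_mean_ms: float = 800.0
    pursuit_bout_mean_s: float = 2.5
    saccade_dur_base_ms: float = 21.0  # main-sequence duration intercept
    saccade_dur_per_deg_ms: float = 2.2
    osc_amp: float = 3.0               # deg/s velocity oscillation amplitude
    osc_period_ms: float = 400.0
    noise_sd: float = 0.1              # deg, per eye, per 500 Hz sample
    blink_rate: float = 4.0            # events/min
    blink_dur_ms: float = 150.0
    sample_rate: float = 500.0
    catchup_err: float = 1.5           # deg position error triggering a CS
    catchup_dir_change: float = 30.0   # deg target direction change triggering a CS
    cs_min_amp: float = 1.4            # deg; smaller errors are absorbed smoothly
    pursuit_prob: float = 0.55         # chance to start pursuit after exploring
    pursuit_radius: float = 8.0        # deg, candidate pairs near gaze
    disparity_inject: bool = False     # add a >4 deg binocular disparity episode

    def __post_init__(self) -> None:
        g = self.gain
        if not (0.0 < g <= 1.2):
            raise ValueError("pursuit_gain must be in (0, 1.2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def gain(self) -> float:
        if self.pursuit_gain is not None:
            return self.pursuit_gain
        return 0.75 if self.strategy == "group" else 0.97


@dataclass
class LabeledGaze:
    time: np.ndarray                   # s, 500 Hz
    left_xy: np.ndarray                # (n, 2) deg, NaN during blinks
    right_xy: np.ndarray
    truth_events: list                 # BasicEvent ground truth
    truth_complex: list                # ComplexEvent ground truth
    pursuit_bouts: list                # (i0, i1, frozenset agents) sample ranges
    clean_frames: FusedGaze            # noiseless gaze at the display rate
    params: ObserverParams | None = None
    seed: int | None = None
    segments: list = field(default_factory=list)  # planned (kind, i0, i1)


def density_saccade_target(traj: TrialTrajectory, t: float,
                           rng: np.random.Generator, kernel_sd: float = 2.0,
                           grid_step: float = 0.25,
                           jitter_sd: float = 0.5) -> np.ndarray:
    """Position of the maximum of the Gaussian-smoothed agent-density map.

    The density at grid point g is sum_i exp(-|g - x_i|^2 / (2 sd^2)) over
    agent positions x_i at time ``t``; the argmax receives Gaussian jitter
    of sd ``jitter_sd``.
    """
    frame = int(np.clip(round(t * traj.frame_rate), 0, traj.n_frames - 1))
    pos = traj.positions[:, frame, :]
    side = traj.params.arena_side if traj.params is not None else 26.0
    ax = np.arange(-side / 2, side / 2 + grid_step / 2, grid_step)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    d2 = (gx[..., None] - pos[:, 0])**2 + (gy[..., None] - pos[:, 1])**2
    dens = np.exp(-d2 / (2 * kernel_sd**2)).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(dens), dens.shape)
    return np.array([ax[i], ax[j]]) + rng.normal(0.0, jitter_sd, size=2)


def _minjerk(n: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n, endpoint=False) + 1.0 / n
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _interp_to_500(traj: TrialTrajectory, n_samples: int, sr: float):
    """Agent positions and velocities resampled to the gaze sample rate."""
    ft = np.arange(traj.n_frames) / traj.frame_rate
    st = np.arange(n_samples) / sr
    pos = np.empty((n_samples, traj.n_agents, 2))
    for a in range(traj.n_agents):
        for c in range(2):
            pos[:, a, c] = np.interp(st, ft, traj.positions[a, :, c])
    vel = np.gradient(pos, 1.0 / sr, axis=0)
    return pos, vel


def _stable_pair(pos500: np.ndarray, i: int, center: np.ndarray,
                 radius: float, sr: float, horizon_s: float = 1.0):
    """The pair with the smallest near-future mean mutual distance.

    Candidate pairs must have their current midpoint within ``radius`` of
    ``center``; distances are averaged over the coming ``horizon_s``
    (subsampled), which favors persistently close pairs -- such as the
    chasing pair -- over transiently close distractors.
    """
    n_s, n_a = pos500.shape[:2]
    sel = np.arange(i, min(i + int(horizon_s * sr), n_s), max(1, int(sr / 20)))
    pos = pos500[sel]  # (k, n_a, 2)
    best, pair = np.inf, None
    for a in range(n_a):
        for b in range(a + 1, n_a):
            mid = 0.5 * (pos[0, a] + pos[0, b])
            if np.hypot(*(mid - center)) > radius:
                continue
            d = np.hypot(*(pos[:, a] - pos[:, b]).T).mean()
            if d < best:
                best, pair = d, (a, b)
    return pair


def simulate_observer(traj: TrialTrajectory, params: ObserverParams,
                      seed: int) -> LabeledGaze:
    """Generate a labeled binocular gaze recording over one trial."""
    p = params
    rng = np.random.default_rng(seed)
    sr = p.sample_rate
    dt = 1.0 / sr
    n = int(round(traj.duration * sr))
    pos500, vel500 = _interp_to_500(traj, n, sr)

    g = np.zeros((n, 2))
    segments: list[tuple] = []   # (kind, i0, i1, agents)
    bouts: list[tuple] = []

    def sacc_dur_samples(amp):
        ms = np.clip(p.saccade_dur_base_ms + p.saccade_dur_per_deg_ms * amp, 25.0, 90.0)
        return max(4, int(round(ms / 1000.0 * sr)))

    def run_saccade(i, target):
        amp = float(np.hypot(*(target - g[i - 1] if i > 0 else target)))
        m = sacc_dur_samples(amp)
        m = min(m, n - i)
        start = g[i - 1] if i > 0 else np.zeros(2)
        g[i:i + m] = start + _minjerk(m)[:, None] * (target - start)
        segments.append(("saccade", i, i + m, frozenset()))
        return i + m

    speed_nom = traj.params.speed if traj.params is not None else 14.5

    def tracked(idx):
        """Tracked-point position/velocity: pair center or single agent."""
        idx = sorted(idx)
        if len(idx) > 1:
            return pos500[:, idx, :].mean(axis=1), vel500[:, idx, :].mean(axis=1)
        return pos500[:, idx[0], :], vel500[:, idx[0], :]

    i = 0
    fix_left = int(rng.integers(1, 4))
    while i < n:
        # ---- fixation ----
        dur = int(np.clip(rng.gamma(4.0, p.fixation_dur_mean_ms / 4.0),
                          150.0, 1200.0) / 1000.0 * sr)
        i1 = min(i + dur, n)
        g[i:i1] = g[max(i - 1, 0)]
        segments.append(("fixation", i, i1, frozenset()))
        i = i1
        if i >= n:
            break
        fix_left -= 1
        if fix_left > 0 or rng.random() >= p.pursuit_prob:
            # ---- exploration saccade to a density maximum ----
            target = density_saccade_target(traj, i * dt, rng)
            i = run_saccade(i, target)
            continue

        # ---- pursuit bout: always targets a close pair ----
        pair = _stable_pair(pos500, min(i, n - 1), g[i - 1],
                            p.pursuit_radius, sr)
        if pair is None:
            fix_left = 1
            continue
        member = int(rng.integers(2))  # tracked member for single_agent
        bout_len = int(np.clip(rng.exponential(p.pursuit_bout_mean_s),
                               0.8, 6.0) * sr)
        bout_end = min(i + bout_len, n)
        bout_start = i
        first = True
        agents = frozenset(pair)
        while i < bout_end - int(0.12 * sr) and i < n - 4:
            if p.strategy == "single_agent":
                cand = frozenset([pair[member if first else 1 - member]])
            else:
                cand = frozenset(pair)
            tp, tv = tracked(cand)
            amp = float(np.hypot(*(tp[i] - g[i - 1])))
            if first or amp >= p.cs_min_amp:
                # catch-up saccade, aimed at the target's predicted position
                agents = cand
                if p.strategy == "single_agent" and not first:
                    member = 1 - member
                m = sacc_dur_samples(amp)
                i = run_saccade(i, tp[min(i + m, n - 1)])
                first = False
                if i >= n - 4 or i >= bout_end:
                    break
            else:
                # small error: pursuit re-aligns smoothly, no saccade
                tp, tv = tracked(agents)
            # ---- smooth movement episode at gain x agent speed ----
            ep_max = int(np.clip(rng.exponential(p.smooth_episode_dur_mean_ms),
                                 200.0, 2000.0) / 1000.0 * sr)
            ep_max = min(ep_max, bout_end - i, n - i)
            if ep_max <= 0:
                break
            tvs = tv[i:i + ep_max]
            speed = np.hypot(tvs[:, 0], tvs[:, 1])
            u = tvs / np.maximum(speed, 1e-9)[:, None]
            phase = (2 * np.pi * np.arange(ep_max) * dt / (p.osc_period_ms / 1000.0)
                     + rng.uniform(0.0, 2 * np.pi))
            vg = (p.gain * speed_nom + p.osc_amp * np.sin(phase))[:, None] * u
            path = g[i - 1] + np.cumsum(vg, axis=0) * dt
            err = np.hypot(*(path - tp[i:i + ep_max]).T)
            ang0 = np.arctan2(tvs[0, 1], tvs[0, 0])
            ang = np.arctan2(tvs[:, 1], tvs[:, 0])
            turn = np.abs(np.degrees((ang - ang0 + np.pi) % (2 * np.pi) - np.pi))
            bad = np.flatnonzero((err > p.catchup_err) |
                                 (turn > p.catchup_dir_change))
            min_ep = int(0.2 * sr)
            stop = ep_max if bad.size == 0 else min(max(int(bad[0]), min_ep), ep_max)
            g[i:i + stop] = path[:stop]
            segments.append(("smooth", i, i + stop, agents))
            i += stop
        bouts.append((bout_start, min(i, n), frozenset(pair)))
        fix_left = int(rng.integers(1, 4))

    # ---- noiseless gaze at the display frame rate + truth labels ----
    clean = _clean_frames(g, traj, sr)
    truth = _truth_events(segments, clean, traj, sr)
    truth_cx = extract_complex(truth)

    # ---- raw binocular output: noise, blinks, optional disparity ----
    left = g + rng.normal(0.0, p.noise_sd, size=g.shape)
    right = g + rng.normal(0.0, p.noise_sd, size=g.shape)
    n_blinks = rng.poisson(p.blink_rate * traj.duration / 60.0)
    bl = max(1, int(p.blink_dur_ms / 1000.0 * sr))
    for b0 in sorted(rng.integers(0, max(1, n - bl), size=n_blinks)):
        left[b0:b0 + bl] = np.nan
        right[b0:b0 + bl] = np.nan
    if p.disparity_inject:
        j0 = n // 3
        right[j0:j0 + int(0.5 * sr), 0] += 6.0

    return LabeledGaze(time=np.arange(n) * dt, left_xy=left, right_xy=right,
                       truth_events=truth, truth_complex=truth_cx,
                       pursuit_bouts=bouts, clean_frames=clean,
                       params=p, seed=seed, segments=segments)


def _clean_frames(g: np.ndarray, traj: TrialTrajectory, sr: float) -> FusedGaze:
    from chasescan.preproc import peak_acceleration
    st = np.arange(len(g)) / sr
    ft = np.arange(traj.n_frames) / traj.frame_rate
    xy = np.column_stack([np.interp(ft, st, g[:, c]) for c in range(2)])
    speed, acc, vel_vec = derive_kinematics(xy, traj.frame_rate)
    return FusedGaze(time=ft, xy=xy, velocity=speed, acceleration=acc,
                     missing_mask=np.zeros(len(ft), dtype=bool),
                     velocity_vec=vel_vec,
                     acc_peak=peak_acceleration(st, g, ft, sr),
                     frame_rate=traj.frame_rate)


def _truth_events(segments, clean: FusedGaze, traj: TrialTrajectory,
                  sr: float, thresholds: EventThresholds = EventThresholds()):
    """Map planned segments to display frames and label them.

    Smooth segments are labeled FSM when the noiseless gaze satisfies the
    pursuit criteria for at least one agent, SSM otherwise; fixations and
    SSMs receive the 4-deg focus sets.
    """
    fr = traj.frame_rate
    # merge back-to-back smooth segments of the same tracked set (episodes
    # whose small error was absorbed without a catch-up saccade)
    merged = []
    for seg in segments:
        if (merged and seg[0] == "smooth" and merged[-1][0] == "smooth"
                and merged[-1][2] == seg[1] and merged[-1][3] == seg[3]):
            merged[-1] = ("smooth", merged[-1][1], seg[2], seg[3])
        else:
            merged.append(seg)
    events = []
    for kind, i0, i1, agents in merged:
        f0 = int(np.ceil(i0 / sr * fr - 1e-9))
        f1 = int(np.ceil(i1 / sr * fr - 1e-9))
        f1 = min(f1, traj.n_frames)
        if f1 <= f0:
            continue
        dur_ms = (f1 - f0) / fr * 1000.0
        if kind == "saccade":
            events.append(BasicEvent("saccade", f0, f1, f0 / fr, f1 / fr))
        elif kind == "fixation":
            if dur_ms > thresholds.fixation_dur_ms:
                foc = focus_set_slow((f0, f1), clean, traj, thresholds)
                events.append(BasicEvent("fixation", f0, f1, f0 / fr, f1 / fr,
                                         frozenset(foc)))
        else:  # smooth
            fsm = (fsm_agent_check((f0, f1), clean, traj, thresholds)
                   if dur_ms > thresholds.fsm_dur_ms else set())
            if fsm:
                events.append(BasicEvent("FSM", f0, f1, f0 / fr, f1 / fr,
                                         frozenset(fsm)))
            elif dur_ms > thresholds.ssm_dur_ms:
                foc = focus_set_slow((f0, f1), clean, traj, thresholds)
                events.append(BasicEvent("SSM", f0, f1, f0 / fr, f1 / fr,
                                         frozenset(foc)))
    return events


def detect_press(gaze: LabeledGaze, traj: TrialTrajectory,
                 min_track_s: float = 1.0, motor_lag_s: float = 0.2):
    """Simulated button press: sustained pursuit of the chasing pair.

    Returns (press_time_s, correct) or (None, False) for an omission.  The
    press fires once a pursuit bout has tracked a set containing both the
    chaser and the chasee for ``min_track_s``, plus a motor lag.
    """
    target = {traj.chaser_idx, traj.chasee_idx}
    sr = gaze.params.sample_rate if gaze.params else 500.0
    for i0, i1, agents in gaze.pursuit_bouts:
        if not target <= set(agents):
            continue
        if (i1 - i0) / sr >= min_track_s:
            t = i0 / sr + min_track_s + motor_lag_s
            if t <= gaze.time[-1]:
                return float(t), True
    return None, False
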