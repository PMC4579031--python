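"""Ideal-observer analysis: templates from chase-centered samples.

The ideal observer knows the chasing pair's identity from the generator,
so its samples are locked halfway between chaser and chasee at a random
time, aligned by the dominant motion direction, and analyzed with the
same PCA / rail-diagram / line-fit machinery as the gaze-event samples.
The chase pattern shows up as two parallel ridges in the PC1 rail
diagram moving at the agent speed.
"""

from __future__ import annotations

import numpy as np

from chasescan.templates import (Lock, SampleSpec, extract_samples, fit_lines,
                                 pca_templates, rail_diagram)

__all__ = ["io_samples", "io_analysis", "io_locks"]

IO_SPEC = SampleSpec(lock_kind="io_random", t_lo=-0.4, t_hi=0.4,
                     spatial_halfwidth=5.0, rotation_source="dominant_direction")


def io_locks(trials, n: int = 5000, seed: int = 0,
             spec: SampleSpec = IO_SPEC) -> list[Lock]:
    """Random chase-midpoint locks, trials weighted by usable duration."""
    if not trials:
        raise ValueError("no trials")
    rng = np.random.default_rng(seed)
    fr = trials[0].frame_rate
    k0 = int(round(spec.t_lo * fr))
    k1 = int(round(spec.t_hi * fr))
    usable = np.array([max(0, tr.n_frames - (k1 - k0) - 1) for tr in trials],
                      dtype=float)
    if usable.sum() == 0:
        raise ValueError("all trials shorter than the sample window")
    weights = usable / usable.sum()
    locks = []
    for ti in rng.choice(len(trials), size=n, p=weights):
        tr = trials[ti]
        frame = int(rng.integers(-k0, tr.n_frames - k1))
        mid = 0.5 * (tr.positions[tr.chaser_idx, frame]
                     + tr.positions[tr.chasee_idx, frame])
        locks.append(Lock(traj=tr, frame=frame, pos=mid))
    return locks


def io_samples(trials, n: int = 5000, seed: int = 0,
               spec: SampleSpec = IO_SPEC):
    """Extract exactly ``n`` chase-centered aligned samples.

    Locks whose sample cannot be aligned (no agent near the midpoint,
    possible in NC trials when the pair separates widely) are dropped
    and redrawn.
    """
    samples = []
    for attempt in range(20):
        need = n - len(samples)
        if need <= 0:
            break
        locks = io_locks(trials, need, (seed + 65_537 * attempt) % (2**31 - 1),
                         spec)
        samples.extend(extract_samples(locks, spec))
    return samples[:n]


def io_analysis(samples, pixel_size: float = 0.25, halfwidth: float = 5.0,
                k: int = 5, blob_sd: float = 0.5) -> dict:
    """PCA, PC1 rail two-line fit, and chase geometry of IO samples.

    Reports explained-variance percentages, both the fitted line-offset
    difference |p1 - p2| and the empirical inter-ridge distance at the
    lock-time rail row (the two need not agree exactly), and the ridge
    speeds.
    """
    pca = pca_templates(samples, pixel_size=pixel_size, halfwidth=halfwidth,
                        k=k, blob_sd=blob_sd)
    rail = rail_diagram(pca.movies[0], t_rel=pca.t_rel,
                        pixel_size=pixel_size, halfwidth=halfwidth)
    fit = fit_lines(rail, n_lines=2)
    (p1, v1, s1), (p2, v2, s2) = fit.lines
    return {
        "pca": pca,
        "rail": rail,
        "fit": fit,
        "var_percent": (100.0 * pca.var_frac).tolist(),
        "pc1_var_percent": float(100.0 * pca.var_frac[0]),
        "lines": fit.lines,
        "ridge_speeds": (abs(v1), abs(v2)),
        "leading_ridge_speed": max(abs(v1), abs(v2)),
        "line_offset_difference": abs(p1 - p2),
        "inter_ridge_distance_at_lock": _inter_ridge_distance(rail),
        "correlation": fit.correlation,
    }


def _inter_ridge_distance(rail) -> float:
    """Distance between the two strongest local maxima at the lock row."""
    row = rail.values[int(np.argmin(np.abs(rail.t_rel)))]
    peaks = [j for j in range(1, len(row) - 1)
             if row[j] >= row[j - 1] and row[j] >= row[j + 1]]
    peaks.sort(key=lambda j: -row[j])
    if not peaks:
        return float("nan")
    first = peaks[0]
    # the second ridge must be a distinct maximum, not a plateau neighbor
    second = next((j for j in peaks[1:]
                   if abs(rail.x[j] - rail.x[first]) >= 1.0), None)
    if second is None:
        return float("nan")
    a, b = sorted((first, second))
    return float(rail.x[b] - rail.x[a])
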