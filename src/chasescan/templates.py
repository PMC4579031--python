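"""Spatiotemporal template analyses.

Samples are short windows of agent motion, translated so a positional
lock (gaze position, saccade target, or chase midpoint) sits at the
origin and rotated so the alignment axis (gaze direction or the agents'
dominant motion direction) maps onto +x.  Rendered as short movies, the
samples support three template analyses:

* average templates, either by rendering-then-averaging or by
  Nadaraya-Watson style kernel regression directly on the coordinates
  (the two agree exactly for equal-length samples);
* PCA movies via eigendecomposition of the sample Gram matrix;
* rail diagrams -- the movie averaged over a 0.3-deg band around the
  alignment axis, displayed as time x on-axis position -- with ridge
  lines fitted by simplex maximization of the correlation with a summed
  unimodal pattern max(0, 1 - |h/s|^3), h(x,t) = (p + v t - x)/(1 + v^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["SampleSpec", "Lock", "AlignedSample", "TemplateMovie", "RailDiagram",
           "LineFitResult", "PCAResult", "dominant_direction", "extract_samples",
           "render_movie", "npr_template", "pca_templates", "rail_diagram",
           "fit_lines"]


@dataclass(frozen=True)
class SampleSpec:
    """Definition of a sample class (window, lock, alignment, agents)."""

    lock_kind: str = "io_random"    # detection | saccade_onset | sme_* | io_random
    t_lo: float = -0.4              # s relative to the time lock
    t_hi: float = 0.4
    spatial_halfwidth: float = 5.0  # deg (10 x 10 deg window)
    rotation_source: str = "dominant_direction"  # or "gaze_direction"
    agent_filter: str = "all"       # or "pursued_only"

    def __post_init__(self):
        if not self.t_lo < self.t_hi:
            raise ValueError("t_lo must be < t_hi")
        if self.spatial_halfwidth <= 0:
            raise ValueError("spatial_halfwidth must be > 0")


@dataclass
class Lock:
    """One positional/temporal lock from which a sample is cut."""

    traj: object                    # TrialTrajectory
    frame: int                      # lock frame index
    pos: np.ndarray                 # lock position, deg
    gaze_dir: float | None = None   # deg, used when rotation_source=gaze_direction
    agents: frozenset | None = None  # pursued agents (for pursued_only)


@dataclass
class AlignedSample:
    coords: np.ndarray              # (n_frames, n_agents, 2), NaN = cropped/absent
    t_rel: np.ndarray               # s relative to lock, per frame
    angle: float                    # alignment rotation that was removed (deg)

    @property
    def n_frames(self) -> int:
        return len(self.coords)


@dataclass
class TemplateMovie:
    pixels: np.ndarray              # (T, H, W) float32, y index first
    pixel_size: float
    halfwidth: float
    counts: np.ndarray              # contributing samples per frame
    t_rel: np.ndarray | None = None

    @property
    def axis(self) -> np.ndarray:
        """Pixel-center coordinates shared by both axes."""
        n = self.pixels.shape[1]
        return (np.arange(n) + 0.5) * self.pixel_size - self.halfwidth


@dataclass
class RailDiagram:
    values: np.ndarray              # (T, X)
    x: np.ndarray                   # on-axis pixel centers
    t_rel: np.ndarray               # s relative to lock


@dataclass
class LineFitResult:
    lines: list                     # [(p, v, s)] sorted leading-first
    correlation: float
    n_lines: int

    @property
    def p(self) -> float:
        return self.lines[0][0]

    @property
    def v(self) -> float:
        return self.lines[0][1]

    @property
    def s(self) -> float:
        return self.lines[0][2]


@dataclass
class PCAResult:
    movies: np.ndarray              # (k, T, H, W) unit-norm eigen-movies
    var_frac: np.ndarray            # explained-variance fractions, descending
    scores: np.ndarray              # (n_samples, k) projections
    mean: np.ndarray                # (T, H, W) mean movie
    pixel_size: float
    halfwidth: float
    t_rel: np.ndarray | None = None


# ---------------------------------------------------------------------------
# alignment

def dominant_direction(traj, frame_window, lock_pos, radius: float = 5.0,
                       n_bins: int = 36) -> float:
    """Dominant agent motion direction near a positional lock, in deg.

    Mode of a radial histogram (10-deg bins) of per-frame, per-agent
    motion directions over the window, each contribution weighted by a
    circular polynomial window w(d) = max(0, 1 - (d/radius)^2) of the
    agent's distance to the lock; refined by the weighted circular mean
    within the modal bin.
    """
    f0, f1 = frame_window
    f0 = max(f0, 0)
    f1 = min(f1, traj.n_frames)
    pos = traj.positions[:, f0:f1, :]
    d = np.diff(pos, axis=1)
    dirs = np.degrees(np.arctan2(d[..., 1], d[..., 0])) % 360.0
    dist = np.hypot(pos[:, :-1, 0] - lock_pos[0], pos[:, :-1, 1] - lock_pos[1])
    w = np.maximum(0.0, 1.0 - (dist / radius) ** 2)
    if not np.any(w > 0):
        raise ValueError("no agents within the weighting window of the lock")
    bins = (dirs // (360.0 / n_bins)).astype(int) % n_bins
    hist = np.bincount(bins.ravel(), weights=w.ravel(), minlength=n_bins)
    mode = int(np.argmax(hist))
    sel = bins == mode
    ang = np.radians(dirs[sel])
    ws = w[sel]
    return float(np.degrees(np.arctan2((ws * np.sin(ang)).sum(),
                                       (ws * np.cos(ang)).sum())) % 360.0)


def _rotation(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])


def extract_samples(locks: list[Lock], spec: SampleSpec,
                    crop_margin: float = 1.5) -> list[AlignedSample]:
    """Cut, center and rotationally align one sample per lock.

    Agent coordinates are translated so the lock is at the origin and
    rotated by minus the alignment angle, mapping the alignment axis onto
    +x.  Coordinates farther than halfwidth + ``crop_margin`` from the
    window on either axis are set to NaN (the margin keeps rendering
    faithful at the window edge).  Locks whose window exceeds the trial
    are dropped.
    """
    out = []
    for lk in locks:
        traj = lk.traj
        fr = traj.frame_rate
        k0 = int(round(spec.t_lo * fr))
        k1 = int(round(spec.t_hi * fr))
        frames = lk.frame + np.arange(k0, k1)
        if frames[0] < 0 or frames[-1] >= traj.n_frames:
            continue
        if spec.rotation_source == "gaze_direction" and lk.gaze_dir is not None:
            angle = float(lk.gaze_dir)
        else:
            try:
                angle = dominant_direction(traj, (frames[0], frames[-1] + 1),
                                           lk.pos)
            except ValueError:
                continue  # no agents near the lock: alignment undefined
        pos = traj.positions[:, frames, :]
        if spec.agent_filter == "pursued_only":
            if not lk.agents:
                continue
            pos = pos[sorted(lk.agents)]
        rel = pos - np.asarray(lk.pos)[None, None, :]
        rot = rel @ _rotation(angle).T
        coords = np.transpose(rot, (1, 0, 2)).astype(float)  # (T, A, 2)
        lim = spec.spatial_halfwidth + crop_margin
        outside = (np.abs(coords) > lim).any(axis=-1)
        coords[outside] = np.nan
        out.append(AlignedSample(coords=coords,
                                 t_rel=np.arange(k0, k1) / fr,
                                 angle=angle))
    return out


# ---------------------------------------------------------------------------
# rendering and templates

def _grid(halfwidth: float, pixel_size: float) -> np.ndarray:
    n = int(round(2 * halfwidth / pixel_size))
    return (np.arange(n) + 0.5) * pixel_size - halfwidth


def _deposit(frame_px: np.ndarray, ax: np.ndarray, x: float, y: float,
             blob_sd: float, pixel_size: float, halfwidth: float) -> None:
    """Add one unit-peak Gaussian blob to a (H, W) pixel frame."""
    # pixel centers within +/-3 sd of the blob, symmetric under reflection
    r = 3.0 * blob_sd
    eps = 1e-9
    j0 = max(0, int(np.ceil((x - r + halfwidth) / pixel_size - 0.5 - eps)))
    j1 = min(len(ax), int(np.floor((x + r + halfwidth) / pixel_size - 0.5 + eps)) + 1)
    i0 = max(0, int(np.ceil((y - r + halfwidth) / pixel_size - 0.5 - eps)))
    i1 = min(len(ax), int(np.floor((y + r + halfwidth) / pixel_size - 0.5 + eps)) + 1)
    if j1 <= j0 or i1 <= i0:
        return
    gx = np.exp(-((ax[j0:j1] - x) ** 2) / (2 * blob_sd ** 2))
    gy = np.exp(-((ax[i0:i1] - y) ** 2) / (2 * blob_sd ** 2))
    frame_px[i0:i1, j0:j1] += gy[:, None] * gx[None, :]


def render_sample(sample: AlignedSample, pixel_size: float = 0.25,
                  halfwidth: float = 5.0, blob_sd: float = 0.5) -> np.ndarray:
    """Render one aligned sample as a (T, H, W) float32 movie.

    Each agent deposits an isotropic Gaussian blob of sd ``blob_sd`` per
    frame (a smooth stand-in for the 1-deg stimulus ring).
    """
    ax = _grid(halfwidth, pixel_size)
    T = sample.n_frames
    mov = np.zeros((T, len(ax), len(ax)), dtype=np.float32)
    for t in range(T):
        for a in range(sample.coords.shape[1]):
            x, y = sample.coords[t, a]
            if np.isfinite(x) and np.isfinite(y):
                _deposit(mov[t], ax, x, y, blob_sd, pixel_size, halfwidth)
    return mov


def render_movie(samples: list[AlignedSample], pixel_size: float = 0.25,
                 halfwidth: float = 5.0, blob_sd: float = 0.5) -> TemplateMovie:
    """Average template by rendering each sample and averaging the movies.

    Variable-length samples contribute only to the frames they cover.
    """
    if not samples:
        raise ValueError("no samples")
    T = max(s.n_frames for s in samples)
    ax = _grid(halfwidth, pixel_size)
    acc = np.zeros((T, len(ax), len(ax)), dtype=np.float64)
    counts = np.zeros(T, dtype=np.int64)
    for s in samples:
        mov = render_sample(s, pixel_size, halfwidth, blob_sd)
        acc[:s.n_frames] += mov
        counts[:s.n_frames] += 1
    acc /= np.maximum(counts, 1)[:, None, None]
    t_rel = max(samples, key=lambda s: s.n_frames).t_rel
    return TemplateMovie(acc.astype(np.float32), pixel_size, halfwidth,
                         counts, t_rel)


def npr_template(samples: list[AlignedSample], pixel_size: float = 0.25,
                 halfwidth: float = 5.0, kernel_sd: float = 0.5) -> TemplateMovie:
    """Average template by kernel regression on the coordinate data.

    Gaussian spatial kernel of sd ``kernel_sd`` evaluated at the pixel
    centers, normalized by the number of samples contributing to each
    frame; equal to render-then-average for equal-length samples, but
    computed without materializing per-sample movies.
    """
    if not samples:
        raise ValueError("no samples")
    T = max(s.n_frames for s in samples)
    ax = _grid(halfwidth, pixel_size)
    acc = np.zeros((T, len(ax), len(ax)), dtype=np.float64)
    counts = np.zeros(T, dtype=np.int64)
    for s in samples:
        counts[:s.n_frames] += 1
        for t in range(s.n_frames):
            for a in range(s.coords.shape[1]):
                x, y = s.coords[t, a]
                if np.isfinite(x) and np.isfinite(y):
                    _deposit(acc[t], ax, x, y, kernel_sd, pixel_size, halfwidth)
    acc /= np.maximum(counts, 1)[:, None, None]
    t_rel = max(samples, key=lambda s: s.n_frames).t_rel
    return TemplateMovie(acc.astype(np.float32), pixel_size, halfwidth,
                         counts, t_rel)


def pca_templates(samples: list[AlignedSample], pixel_size: float = 0.25,
                  halfwidth: float = 5.0, k: int = 5,
                  blob_sd: float = 0.5, center: bool = False) -> PCAResult:
    """PCA movies by eigendecomposition of the sample Gram matrix.

    Samples must share one length.  By default the second-moment (i.e.,
    uncentered) matrix is decomposed, so that for a unimodal sample
    distribution the first component coincides with the average template;
    pass ``center=True`` for conventional covariance PCA.  The n x n Gram
    matrix route is equivalent to the pixel-space eigendecomposition for
    n < n_pixels.  Eigen-movies are unit-norm with the largest-magnitude
    pixel oriented positive; variance fractions are eigenvalues over
    their total.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    lengths = {s.n_frames for s in samples}
    if len(lengths) != 1:
        raise ValueError("PCA requires equal-length samples")
    T = lengths.pop()
    ax = _grid(halfwidth, pixel_size)
    D = T * len(ax) * len(ax)
    X = np.empty((n, D), dtype=np.float32)
    for i, s in enumerate(samples):
        X[i] = render_sample(s, pixel_size, halfwidth, blob_sd).ravel()
    mean = X.mean(axis=0)
    if center:
        X -= mean[None, :]
    # Gram matrix accumulated in float64 blocks: samples are stored in
    # float32 for memory, but a single-precision product loses the
    # agreement with a dense-covariance eigendecomposition
    gram = np.empty((n, n))
    step = max(1, min(n, int(2**25 // max(D, 1)) or 1))
    for i0 in range(0, n, step):
        Xi = X[i0:i0 + step].astype(np.float64)
        for j0 in range(i0, n, step):
            Xj = X[j0:j0 + step].astype(np.float64)
            block = Xi @ Xj.T
            gram[i0:i0 + step, j0:j0 + step] = block
            if j0 != i0:
                gram[j0:j0 + step, i0:i0 + step] = block.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    k = min(k, n)
    movies = np.empty((k, T, len(ax), len(ax)), dtype=np.float32)
    scores = np.empty((n, k), dtype=np.float64)
    for j in range(k):
        comp = X.T @ evecs[:, j].astype(np.float32)
        nrm = np.linalg.norm(comp)
        if nrm > 0:
            comp = comp / nrm
        if comp[np.argmax(np.abs(comp))] < 0:
            comp = -comp
        movies[j] = comp.reshape(T, len(ax), len(ax))
        scores[:, j] = X @ comp
    var_frac = evals[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(movies=movies, var_frac=var_frac, scores=scores,
                     mean=mean.reshape(T, len(ax), len(ax)),
                     pixel_size=pixel_size, halfwidth=halfwidth,
                     t_rel=samples[0].t_rel)


# ---------------------------------------------------------------------------
# rail diagrams and line fitting

def rail_diagram(movie_or_pixels, t_rel=None, pixel_size=None, halfwidth=None,
                 band: float = 0.15) -> RailDiagram:
    """Time x on-axis-position diagram: movie averaged over |y| <= band."""
    if isinstance(movie_or_pixels, TemplateMovie):
        px = movie_or_pixels.pixels
        ax = movie_or_pixels.axis
        t_rel = movie_or_pixels.t_rel if t_rel is None else t_rel
    else:
        px = np.asarray(movie_or_pixels)
        ax = _grid(halfwidth, pixel_size)
    rows = np.flatnonzero(np.abs(ax) <= band)
    if rows.size == 0:
        raise ValueError("pixel grid too coarse: no rows within the band")
    vals = px[:, rows, :].mean(axis=1)
    if t_rel is None:
        t_rel = np.arange(px.shape[0], dtype=float)
    return RailDiagram(values=np.asarray(vals, dtype=float), x=ax,
                       t_rel=np.asarray(t_rel, dtype=float))


def _unimodal_pattern(params, t, x, geometric=False):
    """Sum of unimodal ridge functions over the (t, x) grid."""
    pat = np.zeros((len(t), len(x)))
    for (p, v, s) in params:
        denom = np.sqrt(1.0 + v * v) if geometric else (1.0 + v * v)
        h = (p + v * t[:, None] - x[None, :]) / denom
        pat += np.maximum(0.0, 1.0 - np.abs(h / s) ** 3)
    return pat


def _corr(a, b):
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def fit_lines(rail: RailDiagram, n_lines: int = 1, init=None,
              geometric: bool = False, normalize: str = "row",
              max_ridge_width: float | None = None) -> LineFitResult:
    """Fit one or two ridge lines to a rail diagram.

    Nelder-Mead over (p, v, s) per line, maximizing the Pearson
    correlation between the rail normalized to [0, 1] and the summed
    unimodal pattern max(0, 1 - |h/s|^3).  p is the on-axis offset at
    the time lock (t = 0), v the ridge slope in deg/s, s the width of
    the maximum.  ``normalize='row'`` rescales each time frame to [0, 1]
    (default; the ridge amplitude of real templates fades toward the
    window edges, which would otherwise dominate the correlation),
    ``'global'`` rescales the diagram as a whole.
    """
    vals = rail.values
    rng_v = vals.max() - vals.min()
    if rng_v <= 0:
        raise ValueError("flat rail diagram; fit undefined")
    if normalize == "row":
        lo = vals.min(axis=1, keepdims=True)
        span = vals.max(axis=1, keepdims=True) - lo
        norm = np.where(span > 0, (vals - lo) / np.where(span > 0, span, 1.0), 0.0)
    else:
        norm = (vals - vals.min()) / rng_v
    t, x = rail.t_rel, rail.x

    # Radon-style slope scan: shear the diagram by candidate slopes and
    # score how sharply the rows align; the best shears seed the fit
    v_grid = np.linspace(-30.0, 30.0, 121)
    scores = np.empty(len(v_grid))
    profiles = []
    for gi, v in enumerate(v_grid):
        acc = np.zeros_like(x)
        for i in range(len(t)):
            acc += np.interp(x + v * t[i], x, norm[i], left=0.0, right=0.0)
        scores[gi] = acc.max()
        profiles.append(acc)
    g_best = int(np.argmax(scores))
    v0 = float(v_grid[g_best])
    prof = profiles[g_best]
    p0 = float(x[np.argmax(prof)])

    p_lim = (float(x.min()) - 2.0, float(x.max()) + 2.0)
    # the unimodal function models the ridge of individual 1-deg rings;
    # cap its effective on-axis half-width (s times the h denominator) so
    # the fit cannot blanket the diagram with near-flat broad bands
    max_width = max_ridge_width if max_ridge_width is not None \
        else (3.0 if n_lines == 2 else 6.0)

    def objective(theta):
        params = [tuple(theta[3 * i:3 * i + 3]) for i in range(n_lines)]
        for (p, v, s) in params:
            denom = np.sqrt(1.0 + v * v) if geometric else (1.0 + v * v)
            if s <= 1e-6 or s * denom > max_width or abs(v) > 60.0 \
                    or not p_lim[0] <= p <= p_lim[1]:
                return 1.0
        if n_lines == 2:
            # the two rails model two distinct agents of one chase:
            # near-parallel slopes, offsets at least a ring diameter apart
            if abs(params[0][1] - params[1][1]) > 1.5 or \
                    abs(params[0][0] - params[1][0]) < 1.0:
                return 1.0
        return -_corr(norm, _unimodal_pattern(params, t, x, geometric))

    # the two strongest aligned tracks of the best shear seed the offsets
    peaks = [j for j in range(1, len(prof) - 1)
             if prof[j] >= prof[j - 1] and prof[j] >= prof[j + 1]]
    peaks.sort(key=lambda j: -prof[j])
    peak_x = [float(x[peaks[0]])] if peaks else []
    for j in peaks[1:]:
        if abs(float(x[j]) - peak_x[0]) >= 1.0:
            peak_x.append(float(x[j]))
            break

    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float).ravel())
    denom0 = np.sqrt(1.0 + v0 * v0) if geometric else (1.0 + v0 * v0)
    for w0 in (0.8, 1.5, 2.5):       # effective ridge widths in deg
        s0 = w0 / denom0
        if n_lines == 1:
            for dp in ([0.0, 1.0, -1.0] + ([peak_x[0] - p0] if peak_x else [])):
                starts.append(np.array([p0 + dp, v0, s0]))
        else:
            # seed at the two detected rail maxima; a broad multi-start
            # drifts off the ridge pair when its amplitude fades toward
            # the window edges
            if len(peak_x) == 2 and abs(peak_x[0] - peak_x[1]) >= 1.0:
                q1, q2 = max(peak_x), min(peak_x)
                starts.append(np.array([q1, v0, s0, q2, v0, s0]))
            else:
                starts.append(np.array([p0 + 1.75, v0, s0, p0 - 1.75, v0, s0]))
    # a compact initial simplex keeps the descent in the basin of the
    # seeded ridge configuration instead of drifting down the amplitude
    # gradient of the rail
    best = None
    for th0 in starts:
        steps = np.tile([0.3, 0.5, 0.0], n_lines)
        steps[2::3] = 0.3 * th0[2::3]
        simplex = np.vstack([th0] + [th0 + steps[j] * np.eye(len(th0))[j]
                                     for j in range(len(th0))])
        res = minimize(objective, th0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 4000,
                                "initial_simplex": simplex})
        if best is None or res.fun < best.fun:
            best = res
    params = [tuple(float(u) for u in best.x[3 * i:3 * i + 3])
              for i in range(n_lines)]
    params = [(p, v, abs(s)) for (p, v, s) in params]
    params.sort(key=lambda q: -q[0])  # leading ridge (largest offset) first
    return LineFitResult(lines=params, correlation=float(-best.fun),
                         n_lines=n_lines)
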