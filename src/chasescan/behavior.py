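"""Detection-behavior summaries: log-normal times, Bernoulli rates.

Detection times y follow log(y) ~ N(mu, sigma); the mean detection time
is exp(mu + sigma^2/2).  Parameters are maximum-likelihood estimates
with percentile-bootstrap confidence intervals.  Detection successes are
modeled as Bernoulli; omissions count as incorrect and are excluded from
the detection-time fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogNormalFit", "fit_lognormal", "fit_bernoulli", "rolling_accuracy"]


@dataclass
class LogNormalFit:
    mu: float
    sigma: float
    mean_time: float                 # exp(mu + sigma^2/2), s
    ci: tuple                        # percentile bootstrap CI for mean_time
    n: int


def fit_lognormal(times, n_boot: int = 1000, seed: int = 0,
                  ci_level: float = 0.95) -> LogNormalFit:
    """ML log-normal fit of detection times with bootstrap CI of the mean."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 detection times")
    if np.any(times <= 0):
        raise ValueError("detection times must be positive")
    logs = np.log(times)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    mean_time = float(np.exp(mu + sigma**2 / 2.0))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ls = rng.choice(logs, size=logs.size, replace=True)
        boots[b] = np.exp(ls.mean() + ls.std(ddof=0)**2 / 2.0)
    a = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [a, 1.0 - a])
    return LogNormalFit(mu=mu, sigma=sigma, mean_time=mean_time,
                        ci=(float(lo), float(hi)), n=times.size)


def fit_bernoulli(successes, n_boot: int = 1000, seed: int = 0,
                  ci_level: float = 0.95) -> dict:
    """ML detection rate with percentile-bootstrap CI."""
    s = np.asarray(successes, dtype=bool)
    if s.size == 0:
        raise ValueError("need at least one trial")
    rate = float(s.mean())
    rng = np.random.default_rng(seed)
    boots = rng.binomial(s.size, rate, size=n_boot) / s.size
    a = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [a, 1.0 - a])
    return {"rate": rate, "ci": (float(lo), float(hi)), "n": int(s.size)}


def rolling_accuracy(successes, window: int = 10) -> np.ndarray:
    """Mean success per consecutive ``window``-trial block (the feedback
    subjects saw every ten trials)."""
    s = np.asarray(successes, dtype=float)
    n_blocks = len(s) // window
    if n_blocks == 0:
        return np.empty(0)
    return s[:n_blocks * window].reshape(n_blocks, window).mean(axis=1)
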