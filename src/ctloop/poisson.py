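"""Poisson spike-train generators with independently controlled rate and synchrony.

The shared-probability construction builds an ensemble of spike trains whose
pairwise synchrony is graded by a single parameter ``shared_prob`` (p) while
every train keeps the same marginal firing rate:

* one *shared* train S and, per ensemble member k, one *individual* train I_k
  are drawn, all homogeneous Poisson at the target rate;
* each spike of S is copied into member k independently with probability p;
* each spike of I_k is kept with probability 1 - p.

The marginal rate of member k is then p*rate + (1-p)*rate = rate for every p,
while any two members share S-spikes with probability p^2, giving an exact-
coincidence excess of p^2 * rate coincidences/s on top of the independence
baseline.  Shared spikes keep identical timestamps across members unless a
jitter is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_data import SpikeTrain

__all__ = [
    "SharedPoissonConfig",
    "gen_poisson",
    "gen_shared_poisson",
    "gen_inhomogeneous_poisson",
]


@dataclass(frozen=True)
class SharedPoissonConfig:
    """Configuration of a shared-probability correlated Poisson ensemble.

    Defaults mirror the corticothalamic drive used by the circuit model:
    35 L6CT inputs at 2.5 spikes/s.
    """

    n_trains: int = 35
    rate: float = 2.5
    shared_prob: float = 0.0
    duration: float = 1.0
    seed: int = 0
    jitter_sd: float = 0.0  # s; jitter applied to copied shared spikes

    def __post_init__(self):
        if not 0.0 <= self.shared_prob <= 1.0:
            raise ValueError("shared_prob must be in [0, 1]")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.n_trains < 1:
            raise ValueError("n_trains must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def _dedupe_sorted(t: np.ndarray) -> np.ndarray:
    """Strictly increasing version of sorted ``t`` (drops exact duplicates)."""
    if t.size < 2:
        return t
    keep = np.empty(t.size, dtype=bool)
    keep[0] = True
    np.greater(t[1:], t[:-1], out=keep[1:])
    return t[keep]


def gen_poisson(rate: float, duration: float, seed) -> SpikeTrain:
    """Homogeneous Poisson spike train via exponential inter-arrival sampling.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if rate == 0:
        return SpikeTrain(np.empty(0), duration)
    # Draw in blocks of exponential gaps until past the end.
    times = []
    t = 0.0
    block = max(16, int(rate * duration * 1.25) + 16)
    while t < duration:
        gaps = rng.exponential(1.0 / rate, size=block)
        cum = t + np.cumsum(gaps)
        times.append(cum[cum < duration])
        t = cum[-1]
    times = np.concatenate(times) if times else np.empty(0)
    return SpikeTrain(times, duration)


def gen_shared_poisson(config: SharedPoissonConfig) -> list:
    """Ensemble of correlated Poisson trains (shared-probability construction).

    Returns ``config.n_trains`` :class:`SpikeTrain` objects.  Reproducible
    under ``config.seed``; each train's marginal rate equals ``config.rate``
    in expectation for every ``shared_prob``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.shared_prob
    shared = gen_poisson(config.rate, config.duration, rng).times
    out = []
    for _k in range(config.n_trains):
        indiv = gen_poisson(config.rate, config.duration, rng).times
        take_shared = shared[rng.random(shared.size) < p]
        if config.jitter_sd > 0 and take_shared.size:
            take_shared = take_shared + rng.normal(0, config.jitter_sd, take_shared.size)
            take_shared = np.clip(take_shared, 0.0, config.duration)
        take_indiv = indiv[rng.random(indiv.size) < (1.0 - p)]
        t = np.sort(np.concatenate([take_shared, take_indiv]))
        out.append(SpikeTrain(_dedupe_sorted(t), config.duration))
    return out


def gen_inhomogeneous_poisson(rate_profile, dt: float, duration: float, seed) -> SpikeTrain:
    """Inhomogeneous Poisson train by thinning against the profile maximum.

    ``rate_profile`` gives the rate (spikes/s) on the uniform grid
    ``t = i*dt``; values are held piecewise-constant over each dt bin.  The
    expected count over any interval equals the integral of the profile.
    """
    prof = np.asarray(rate_profile, dtype=float)
    if np.any(prof < 0):
        raise ValueError("rate_profile must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rmax = prof.max() if prof.size else 0.0
    if rmax == 0:
        return SpikeTrain(np.empty(0), duration)
    cand = gen_poisson(rmax, duration, rng).times
    idx = np.minimum((cand / dt).astype(int), prof.size - 1)
    keep = rng.random(cand.size) < prof[idx] / rmax
    return SpikeTrain(cand[keep], duration)
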