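"""Spike-train measures: cross-correlograms, pairwise synchrony strength,
PSTHs, ongoing/sensory rate quantification, and thalamic burst detection.

The synchrony strength for a pair of units counts spike coincidences within
+/- 7.5 ms and normalizes by the root mean square of the two squared spike
counts::

    strength = sum(ccg[-7.5 ms : +7.5 ms]) / sqrt((N1**2 + N2**2) / 2)

Coincidences are counted by exact pair enumeration (no lag binning) and the
+/-7.5 ms window is inclusive at the boundary.  The statistic is symmetric,
translation invariant and equals 1.0 for identical sparse trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_data import AlignedRaster, SpikeTrain

__all__ = [
    "PairSynchrony",
    "PSTH",
    "cross_correlogram",
    "coincidence_count",
    "synchrony_strength",
    "pair_synchrony",
    "synchrony_timecourse",
    "psth",
    "grand_psth",
    "ongoing_rate_change",
    "sensory_response",
    "detect_bursts",
]

SYNC_HALF_WIDTH = 0.0075  # s; +/- window over the cross-correlogram


@dataclass
class PairSynchrony:
    unit_a: str
    unit_b: str
    lags: np.ndarray          # lag-bin centers, s
    ccg: np.ndarray           # counts per lag bin
    n1: int
    n2: int
    strength: float


@dataclass
class PSTH:
    """Per-bin firing rate (spikes/s) aligned to an event."""
    edges: np.ndarray         # bin edges, s relative to the event
    rate: np.ndarray          # spikes/s per bin
    n_trials: int
    sem: np.ndarray | None = None   # across units, for grand PSTHs

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _times(x) -> np.ndarray:
    return x.times if isinstance(x, SpikeTrain) else np.asarray(x, dtype=float)


def cross_correlogram(a, b, max_lag: float, bin_width: float = 0.001):
    """Lag-binned counts of spike pairs with ``t_b - t_a`` in each bin.

    Returns ``(lag_centers, counts)``; bins tile ``[-max_lag, max_lag]``.
    """
    if max_lag <= 0 or bin_width <= 0:
        raise ValueError("max_lag and bin_width must be > 0")
    ta, tb = _times(a), _times(b)
    n_bins = int(round(2 * max_lag / bin_width))
    edges = -max_lag + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    if ta.size and tb.size:
        lo = np.searchsorted(tb, ta - max_lag, side="left")
        hi = np.searchsorted(tb, ta + max_lag, side="right")
        for i in range(ta.size):
            if hi[i] > lo[i]:
                d = tb[lo[i]:hi[i]] - ta[i]
                counts += np.histogram(d, bins=edges)[0]
    return 0.5 * (edges[:-1] + edges[1:]), counts


def coincidence_count(a, b, half_width: float = SYNC_HALF_WIDTH) -> int:
    """Number of spike pairs with ``|t_b - t_a| <= half_width`` (inclusive)."""
    ta, tb = _times(a), _times(b)
    if not ta.size or not tb.size:
        return 0
    lo = np.searchsorted(tb, ta - half_width, side="left")
    hi = np.searchsorted(tb, ta + half_width, side="right")
    return int(np.sum(hi - lo))


def synchrony_strength(a, b, half_width: float = SYNC_HALF_WIDTH) -> float:
    """Pairwise synchrony strength (coincidences over RMS spike count).

    Raises ValueError when both trains are empty (the statistic is 0/0).
    A single empty train gives 0.0.
    """
    ta, tb = _times(a), _times(b)
    n1, n2 = ta.size, tb.size
    if n1 == 0 and n2 == 0:
        raise ValueError("synchrony strength undefined for two empty trains")
    denom = np.sqrt((n1 ** 2 + n2 ** 2) / 2.0)
    return coincidence_count(ta, tb, half_width) / denom


def pair_synchrony(unit_a: str, a, unit_b: str, b,
                   max_lag: float = SYNC_HALF_WIDTH,
                   bin_width: float = 0.001) -> PairSynchrony:
    """Bundle the cross-correlogram and the synchrony strength for one pair."""
    lags, ccg = cross_correlogram(a, b, max_lag, bin_width)
    ta, tb = _times(a), _times(b)
    return PairSynchrony(
        unit_a=unit_a, unit_b=unit_b, lags=lags, ccg=ccg,
        n1=ta.size, n2=tb.size,
        strength=synchrony_strength(ta, tb),
    )


def mean_pairwise_strength(trains, half_width: float = SYNC_HALF_WIDTH) -> float:
    """Mean synchrony strength over all unordered pairs of an ensemble.

    Pairs where both trains are empty are skipped.
    """
    vals = []
    for i in range(len(trains)):
        for j in range(i + 1, len(trains)):
            ti, tj = _times(trains[i]), _times(trains[j])
            if ti.size == 0 and tj.size == 0:
                continue
            vals.append(synchrony_strength(ti, tj, half_width))
    if not vals:
        raise ValueError("no scorable pairs")
    return float(np.mean(vals))


def synchrony_timecourse(raster_a: AlignedRaster, raster_b: AlignedRaster,
                         window: float = 0.100, step: float = 0.010,
                         half_width: float = SYNC_HALF_WIDTH):
    """Time-resolved synchrony strength between two units.

    Spikes are pooled across trials within each sliding window before the
    strength is computed.  Windows with zero spikes from both units are
    reported as NaN (missing), not zero.  Returns ``(window_centers, values)``.
    """
    if raster_a.n_trials != raster_b.n_trials:
        raise ValueError("rasters must have the same trial count")
    t0, t1 = raster_a.window_start, raster_a.window_end
    starts = np.arange(t0, t1 - window + 1e-12, step)
    pooled_a = raster_a.pooled()
    pooled_b = raster_b.pooled()
    centers = starts + window / 2.0
    vals = np.full(starts.size, np.nan)
    for k, s in enumerate(starts):
        sa = pooled_a[(pooled_a >= s) & (pooled_a < s + window)]
        sb = pooled_b[(pooled_b >= s) & (pooled_b < s + window)]
        if sa.size or sb.size:
            vals[k] = synchrony_strength(sa, sb, half_width)
    return centers, vals


# ---------------------------------------------------------------------------
# PSTHs
# ---------------------------------------------------------------------------

def psth(raster: AlignedRaster, bin_width: float = 0.010) -> PSTH:
    """Trial-averaged firing rate per bin: count / (n_trials * bin_width)."""
    if raster.n_trials == 0:
        raise ValueError("PSTH of a zero-trial raster is undefined")
    n_bins = int(round((raster.window_end - raster.window_start) / bin_width))
    edges = raster.window_start + bin_width * np.arange(n_bins + 1)
    counts = np.histogram(raster.pooled(), bins=edges)[0]
    return PSTH(edges=edges, rate=counts / (raster.n_trials * bin_width),
                n_trials=raster.n_trials)


def grand_psth(psths) -> PSTH:
    """Mean +/- sem across units of per-unit PSTHs with identical binning."""
    if not psths:
        raise ValueError("no PSTHs")
    edges = psths[0].edges
    for p in psths[1:]:
        if not np.allclose(p.edges, edges):
            raise ValueError("PSTHs must share bin edges")
    rates = np.vstack([p.rate for p in psths])
    sem = rates.std(axis=0, ddof=1) / np.sqrt(rates.shape[0]) \
        if rates.shape[0] > 1 else np.zeros(rates.shape[1])
    return PSTH(edges=edges, rate=rates.mean(axis=0),
                n_trials=psths[0].n_trials, sem=sem)


# ---------------------------------------------------------------------------
# Rate-change quantification
# ---------------------------------------------------------------------------

def _counts_in(raster: AlignedRaster, lo: float, hi: float) -> np.ndarray:
    return np.array([np.sum((t >= lo) & (t < hi)) for t in raster.trials])


def ongoing_rate_change(raster: AlignedRaster,
                        drive_window=(0.250, 0.750),
                        baseline_window=(-0.500, 0.000)):
    """Per-trial LED-driven change in ongoing rate, and its trial mean.

    The default drive window starts at the end of the 250 ms LED ramp and
    spans the 500 ms hold epoch; the baseline is the equal-length pre-LED
    window.  Returns ``(per_trial_delta, mean_delta)`` in spikes/s.  Pass
    e.g. ``drive_window=(0.700, 0.750), baseline_window=(-0.050, 0.000)`` to
    restrict the quantification to the last 50 ms of the hold.
    """
    d0, d1 = drive_window
    b0, b1 = baseline_window
    if raster.window_start > b0 or raster.window_end < d1:
        raise ValueError(
            f"raster window [{raster.window_start}, {raster.window_end}) does "
            f"not cover the quantification windows"
        )
    delta = (_counts_in(raster, d0, d1) / (d1 - d0)
             - _counts_in(raster, b0, b1) / (b1 - b0))
    return delta, float(delta.mean())


def sensory_response(raster: AlignedRaster, window: float = 0.030):
    """Per-trial baseline-subtracted evoked rate around a punctate stimulus.

    Rate in ``[0, window)`` minus rate in ``[-window, 0)`` per trial;
    returns ``(per_trial_delta, mean_delta)`` in spikes/s.
    """
    if raster.window_start > -window or raster.window_end < window:
        raise ValueError("raster does not cover the +/- sensory window")
    delta = (_counts_in(raster, 0.0, window)
             - _counts_in(raster, -window, 0.0)) / window
    return delta, float(delta.mean())


# ---------------------------------------------------------------------------
# Burst detection
# ---------------------------------------------------------------------------

def detect_bursts(train, silence: float = 0.100, isi_max: float = 0.004,
                  t_start: float | None = 0.0):
    """Detect T-type-like bursts: >= 2 spikes with ISIs < ``isi_max``,
    preceded by >= ``silence`` of no spikes.

    A candidate burst at the very first spike qualifies only when the epoch
    start (``t_start``) lies at least ``silence`` before it; pass
    ``t_start=None`` when the recording start is unknown, in which case a
    leading candidate is conservatively excluded.

    Returns a list of ``(start_index, n_spikes)`` tuples; bursts do not
    overlap and every burst has at least 2 spikes.
    """
    t = _times(train)
    bursts = []
    n = t.size
    i = 0
    while i < n - 1:
        if i == 0:
            quiet = t_start is not None and (t[0] - t_start) >= silence
        else:
            quiet = (t[i] - t[i - 1]) >= silence
        if quiet and (t[i + 1] - t[i]) < isi_max:
            j = i + 1
            while j + 1 < n and (t[j + 1] - t[j]) < isi_max:
                j += 1
            bursts.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1
    return bursts


def burst_spike_indices(train, **kw) -> np.ndarray:
    """Indices of all spikes participating in any detected burst."""
    idx = []
    for start, count in detect_bursts(train, **kw):
        idx.extend(range(start, start + count))
    return np.asarray(idx, dtype=int)
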