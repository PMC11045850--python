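"""Unit classification: RS/FS waveform typing, opto-tagging of L6CT units,
the 2-of-3 stimulus-responsiveness test, and VPm/TRN inclusion criteria.

All procedures are pure functions of their inputs plus an explicit seed for
the bootstrap/baseline resampling, so identical inputs always give identical
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spike_data import AlignedRaster

__all__ = [
    "ClassificationResult",
    "classify_rs_fs",
    "opto_tag_test",
    "classify_l6ct",
    "stimulus_responsive_test",
    "vpm_trn_criteria",
    "wilcoxon_paired",
]

RS_THRESHOLD_MS = 0.5   # trough-to-peak > 0.5 ms -> regular spiking
FS_THRESHOLD_MS = 0.4   # trough-to-peak < 0.4 ms -> fast spiking
OPTO_TAG_ALPHA = 0.01
VPM_MIN_TPT_MS = 0.3    # narrower units in VPm treated as TRN axons
FIRST_STIM_MAX_LATENCY = 0.015   # s, first deflection of the adapting train
LAST_STIM_MAX_LATENCY = 0.020    # s, last deflection


@dataclass
class ClassificationResult:
    unit_id: str
    labels: set = field(default_factory=set)
    p_values: dict = field(default_factory=dict)
    passed: dict = field(default_factory=dict)
    primary_whisker: str | None = None


def wilcoxon_paired(x, y):
    """Two-sided Wilcoxon signed-rank on paired samples, zeros discarded.

    Exact null distribution for n <= 25 retained pairs, normal approximation
    above.  Returns the p-value; 1.0 when no pair differs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    mode = "exact" if d.size <= 25 else "approx"
    return float(stats.wilcoxon(d, zero_method="wilcox", mode=mode,
                                alternative="two-sided").pvalue)


def classify_rs_fs(tpt_ms: float) -> str:
    """Waveform class from the trough-to-peak time (ms).

    > 0.5 ms -> 'RS'; < 0.4 ms -> 'FS'; widths in [0.4, 0.5] ms are left
    'unclassified' (such units are excluded from analysis).
    """
    if not tpt_ms > 0:
        raise ValueError("tpt_ms must be positive")
    if tpt_ms > RS_THRESHOLD_MS:
        return "RS"
    if tpt_ms < FS_THRESHOLD_MS:
        return "FS"
    return "unclassified"


# ---------------------------------------------------------------------------
# Opto-tagging (stimulus-associated spike-latency test)
# ---------------------------------------------------------------------------

def _latency_hist(latencies, window: float, bin_width: float) -> np.ndarray:
    """Normalized first-spike-latency histogram, conditioned on spiking.

    Trials without a spike in the window are excluded: the test targets the
    *shape* of the latency distribution (temporal jitter), not the firing
    rate.  Add-one (Laplace) smoothing regularizes the sparse histograms a
    low-rate unit produces in short baseline windows, so that genuine
    concentration in one bin, not sampling sparseness, drives the
    divergence.
    """
    n_bins = int(round(window / bin_width))
    h = np.zeros(n_bins)
    for lat in latencies:
        if lat is not None and not np.isnan(lat):
            h[min(int(lat / bin_width), n_bins - 1)] += 1
    h = h + 1.0
    return h / h.sum()


def _first_latencies(raster: AlignedRaster, window: float) -> np.ndarray:
    out = np.full(raster.n_trials, np.nan)
    for k, t in enumerate(raster.trials):
        post = t[(t >= 0) & (t < window)]
        if post.size:
            out[k] = post[0]
    return out


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def opto_tag_test(pulse_raster: AlignedRaster, baseline_train,
                  baseline_epoch: tuple, n_baseline: int = 100,
                  window: float = 0.010, bin_width: float = 0.001,
                  alpha: float = OPTO_TAG_ALPHA, seed: int = 0):
    """Rank-based first-spike-latency test for optogenetic tagging.

    Compares the distribution of first spike latencies after brief (5 ms)
    light pulses against latency distributions measured in ``n_baseline``
    equal-length windows drawn from spontaneous activity.  The divergence
    statistic is the median Jensen-Shannon divergence between a window's
    latency histogram (1 ms bins over ``window``, conditioned on a spike
    occurring so that temporal jitter rather than rate drives the statistic)
    and every baseline histogram; the p-value is the rank of the pulse
    window's statistic among the baseline windows' null statistics.

    This follows the published SALT logic (latency distributions, rank-based
    significance) without reproducing its exact internals.

    Parameters
    ----------
    pulse_raster : spikes aligned to pulse onsets, window covering [0, window).
    baseline_train : SpikeTrain (recording time) supplying spontaneous epochs.
    baseline_epoch : (start, end) seconds of recording time free of stimuli.
    Returns ``(p_value, tagged)``.
    """
    if pulse_raster.n_trials < 2:
        raise ValueError("need at least 2 pulse trials")
    b0, b1 = baseline_epoch
    if b1 - b0 < (n_baseline + 1) * window:
        raise ValueError("baseline epoch too short for the requested windows")
    rng = np.random.default_rng(seed)
    n_trials = pulse_raster.n_trials

    hist_test = _latency_hist(_first_latencies(pulse_raster, window),
                              window, bin_width)

    from .spike_data import align_to_events
    base_hists = []
    for _ in range(n_baseline):
        starts = rng.uniform(b0, b1 - window, size=n_trials)
        r = align_to_events(baseline_train, starts, 0.0, window)
        base_hists.append(_latency_hist(_first_latencies(r, window),
                                        window, bin_width))
    base_hists = np.asarray(base_hists)

    def median_div(h, others):
        return float(np.median([_js_divergence(h, o) for o in others]))

    d_test = median_div(hist_test, base_hists)
    d_null = np.array([
        median_div(base_hists[i], np.delete(base_hists, i, axis=0))
        for i in range(n_baseline)
    ])
    p = (1 + int(np.sum(d_null >= d_test))) / (n_baseline + 1)
    return p, p < alpha


def classify_l6ct(unit_meta, pulse_raster, baseline_train, baseline_epoch,
                  alpha: float = OPTO_TAG_ALPHA, seed: int = 0,
                  **kw) -> ClassificationResult:
    """Full L6CT gate: opto-tag p < alpha AND regular-spiking AND deep layer.

    The depth gate applies only when the unit has a layer label; without one
    the gate is skipped with a warning.
    """
    res = ClassificationResult(unit_id=unit_meta.unit_id)
    p, latency_ok = opto_tag_test(pulse_raster, baseline_train,
                                  baseline_epoch, alpha=alpha, seed=seed, **kw)
    res.p_values["opto_tag"] = p
    res.passed["opto_tag"] = latency_ok
    wf = classify_rs_fs(unit_meta.tpt_ms) if unit_meta.tpt_ms else "unclassified"
    res.passed["RS"] = wf == "RS"
    if wf != "unclassified":
        res.labels.add(wf)
    if unit_meta.layer is None:
        warnings.warn(f"unit {unit_meta.unit_id}: no layer label; "
                      f"depth gate for opto-tagging skipped")
        deep = True
    else:
        deep = unit_meta.layer in ("5", "6")
    res.passed["deep"] = deep
    if latency_ok and res.passed["RS"] and deep:
        res.labels.add("L6CT")
    return res


# ---------------------------------------------------------------------------
# 2-of-3 stimulus-responsiveness test
# ---------------------------------------------------------------------------

def _bootstrap_ci(values, n_boot: int, rng, level: float = 0.95):
    """Percentile CI of the mean under trial resampling."""
    values = np.asarray(values, dtype=float)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


def stimulus_responsive_test(raster: AlignedRaster, window: float = 0.050,
                             psth_bin: float = 0.010, n_boot: int = 1000,
                             seed: int = 0) -> ClassificationResult:
    """Three subtests on 50 ms pre/post-stimulus windows; responsive = >= 2 pass.

    1. Two-sided Wilcoxon signed-rank on pre vs post spike counts (p < 0.05).
    2. Zero outside the 95% bootstrap CI of the per-trial (post - pre) counts.
    3. In the post-stimulus PSTH (10 ms bins), >= 3 bins above or >= 2 bins
       below the 95% bootstrap CI of pre-stimulus per-bin activity.
    """
    if raster.n_trials < 10:
        raise ValueError("need >= 10 trials")
    if raster.window_start > -window or raster.window_end < window:
        raise ValueError("raster must cover the pre/post windows")
    rng = np.random.default_rng(seed)
    res = ClassificationResult(unit_id=raster.unit_id)

    pre = np.array([np.sum((t >= -window) & (t < 0)) for t in raster.trials])
    post = np.array([np.sum((t >= 0) & (t < window)) for t in raster.trials])

    if pre.sum() == 0 and post.sum() == 0:
        warnings.warn(f"unit {raster.unit_id}: no spikes in the test windows; "
                      f"declared non-responsive")
        res.passed = {"wilcoxon": False, "bootstrap_ci": False, "psth_bins": False}
        res.p_values["wilcoxon"] = 1.0
        return res

    p1 = wilcoxon_paired(post, pre)
    res.p_values["wilcoxon"] = p1
    res.passed["wilcoxon"] = p1 < 0.05

    lo, hi = _bootstrap_ci(post - pre, n_boot, rng)
    res.passed["bootstrap_ci"] = not (lo <= 0.0 <= hi)

    # Subtest 3: post-stimulus PSTH bins against the CI of per-bin (10 ms)
    # pre-stimulus counts under trial resampling.
    n_bins = int(round(window / psth_bin))
    pre_per_bin = pre / n_bins
    lo_b, hi_b = _bootstrap_ci(pre_per_bin, n_boot, rng)
    post_bins = np.array([
        np.mean([np.sum((t >= b * psth_bin) & (t < (b + 1) * psth_bin))
                 for t in raster.trials])
        for b in range(n_bins)
    ])
    above = int(np.sum(post_bins > hi_b))
    below = int(np.sum(post_bins < lo_b))
    res.passed["psth_bins"] = above >= 3 or below >= 2

    if sum(res.passed.values()) >= 2:
        res.labels.add("stimulus_responsive")
    return res


# ---------------------------------------------------------------------------
# VPm / TRN verification
# ---------------------------------------------------------------------------

def _whisker_response(first_raster: AlignedRaster, window: float):
    """(p_increase, mean_delta_count, mean_first_latency or nan)."""
    pre = np.array([np.sum((t >= -window) & (t < 0)) for t in first_raster.trials])
    post = np.array([np.sum((t >= 0) & (t < window)) for t in first_raster.trials])
    p = wilcoxon_paired(post, pre)
    increased = post.mean() > pre.mean()
    lats = _first_latencies(first_raster, window)
    mean_lat = float(np.nanmean(lats)) if np.any(~np.isnan(lats)) else np.nan
    return p, increased, float(post.mean() - pre.mean()), mean_lat


def vpm_trn_criteria(unit_meta, whisker_rasters: dict, region: str,
                     window: float = 0.030, alpha: float = 0.05,
                     ) -> ClassificationResult:
    """VPm/TRN inclusion from responses to a 10 Hz adapting whisker train.

    ``whisker_rasters`` maps whisker name -> (first_raster, last_raster):
    spikes aligned to the first and last deflection of the train, covering
    at least [-window, window).

    A unit is verified when, for at least one whisker, both the first and
    last deflections evoke a significant rate increase (two-sided Wilcoxon,
    p < alpha, with post > pre), mean first-spike latency is < 15 ms (first)
    and < 20 ms (last), and — for VPm only — the waveform trough-to-peak
    exceeds 0.3 ms.  The primary whisker is the one with the largest response
    to the first deflection, ties broken by the earlier latency.
    """
    if region not in ("VPm", "TRN"):
        raise ValueError("region must be 'VPm' or 'TRN'")
    res = ClassificationResult(unit_id=unit_meta.unit_id)

    candidates = []
    for whisker, (first_r, last_r) in whisker_rasters.items():
        if last_r is None:
            raise ValueError(f"whisker {whisker}: missing last-deflection raster")
        p1, inc1, mag1, lat1 = _whisker_response(first_r, window)
        pL, incL, magL, latL = _whisker_response(last_r, window)
        res.p_values[f"{whisker}:first"] = p1
        res.p_values[f"{whisker}:last"] = pL
        ok = (p1 < alpha and inc1 and pL < alpha and incL
              and not np.isnan(lat1) and lat1 < FIRST_STIM_MAX_LATENCY
              and not np.isnan(latL) and latL < LAST_STIM_MAX_LATENCY)
        res.passed[whisker] = ok
        if ok:
            candidates.append((whisker, mag1, lat1))

    waveform_ok = True
    if region == "VPm":
        waveform_ok = (unit_meta.tpt_ms is not None
                       and unit_meta.tpt_ms > VPM_MIN_TPT_MS)
        res.passed["waveform"] = waveform_ok

    if candidates and waveform_ok:
        candidates.sort(key=lambda c: (-c[1], c[2]))  # magnitude desc, latency asc
        res.primary_whisker = candidates[0][0]
        res.labels.add(f"{region}_verified")
    return res
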