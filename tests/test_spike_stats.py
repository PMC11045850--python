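"""Spike-train statistics against brute-force oracles and closed forms."""

import numpy as np
import pytest

from ctloop.poisson import gen_poisson
from ctloop.spike_data import AlignedRaster, SpikeTrain, align_to_events
from ctloop.spike_stats import (
    burst_spike_indices,
    coincidence_count,
    cross_correlogram,
    detect_bursts,
    grand_psth,
    ongoing_rate_change,
    psth,
    sensory_response,
    synchrony_strength,
    synchrony_timecourse,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_strength(a, b, w=0.0075):
    """Exhaustive O(N^2) pair counting for the synchrony statistic."""
    ta = a.times if isinstance(a, SpikeTrain) else np.asarray(a)
    tb = b.times if isinstance(b, SpikeTrain) else np.asarray(b)
    coinc = sum(1 for x in ta for y in tb if abs(y - x) <= w)
    return coinc / np.sqrt((len(ta) ** 2 + len(tb) ** 2) / 2)


def brute_force_bursts(times, silence=0.1, isi=0.004, t_start=0.0):
    """Independent linear scan re-implementing the burst definition."""
    out = []
    n = len(times)
    in_burst_until = -1
    for i in range(n - 1):
        if i <= in_burst_until:
            continue
        if i == 0:
            quiet = t_start is not None and times[0] - t_start >= silence
        else:
            quiet = times[i] - times[i - 1] >= silence
        if quiet and times[i + 1] - times[i] < isi:
            j = i + 1
            while j + 1 < n and times[j + 1] - times[j] < isi:
                j += 1
            out.append((i, j - i + 1))
            in_burst_until = j
    return out


class TestCrossCorrelogram:
    def test_single_pair_at_5ms(self):
        lags, c = cross_correlogram(np.array([1.0]), np.array([1.005]),
                                    max_lag=0.0075, bin_width=0.001)
        assert c.sum() == 1
        assert lags[np.argmax(c)] == pytest.approx(0.005, abs=5e-4)

    def test_identical_sparse_central_bin(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        lags, c = cross_correlogram(t, t, max_lag=0.0075, bin_width=0.001)
        assert c.sum() == 4
        assert c[np.argmin(np.abs(lags))] == 4

    def test_total_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(0, 50, 300))
        b = np.sort(rng.uniform(0, 50, 250))
        _, c = cross_correlogram(a, b, max_lag=0.030, bin_width=0.001)
        brute = sum(1 for x in a for y in b if -0.030 <= y - x < 0.030)
        assert abs(int(c.sum()) - brute) <= 1  # right-edge binning of histogram

    def test_empty_trains(self):
        _, c = cross_correlogram(np.array([]), np.array([1.0]), 0.01)
        assert c.sum() == 0


class TestSynchronyStrength:
    def test_identical_sparse_trains_is_one(self):
        t = np.arange(10) * 0.020  # all ISIs 20 ms > 15 ms
        assert synchrony_strength(t, t) == pytest.approx(1.0)

    def test_one_empty_is_zero(self):
        assert synchrony_strength(np.array([1.0, 2.0]), np.array([])) == 0.0

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            synchrony_strength(np.array([]), np.array([]))

    def test_matches_brute_force_on_poisson_pairs(self):
        rng = np.random.default_rng(123)
        for k in range(25):
            a = gen_poisson(10.0, 30.0, rng)
            b = gen_poisson(10.0, 30.0, rng)
            assert synchrony_strength(a, b) == pytest.approx(
                brute_force_strength(a, b), abs=1e-12)

    def test_independence_level_analytic(self):
        # E[coincidences] = n_a*n_b*2w/T for independent uniform spikes.
        rng = np.random.default_rng(5)
        vals, expect = [], []
        for _ in range(40):
            a = gen_poisson(10.0, 100.0, rng)
            b = gen_poisson(10.0, 100.0, rng)
            vals.append(coincidence_count(a.times, b.times))
            expect.append(a.n_spikes * b.n_spikes * 2 * 0.0075 / 100.0)
        assert np.mean(vals) == pytest.approx(np.mean(expect), rel=0.15)

    def test_symmetry_and_translation_invariance(self):
        rng = np.random.default_rng(9)
        a = gen_poisson(8.0, 20.0, rng)
        b = gen_poisson(12.0, 20.0, rng)
        s = synchrony_strength(a, b)
        assert synchrony_strength(b, a) == pytest.approx(s)
        sh = 13.7
        assert synchrony_strength(a.times + sh, b.times + sh) == pytest.approx(s)

    def test_additive_over_disjoint_epochs(self):
        rng = np.random.default_rng(2)
        a1 = np.sort(rng.uniform(0, 10, 50))
        b1 = np.sort(rng.uniform(0, 10, 50))
        a2 = np.sort(rng.uniform(20, 30, 50))
        b2 = np.sort(rng.uniform(20, 30, 50))
        c_cat = coincidence_count(np.concatenate([a1, a2]),
                                  np.concatenate([b1, b2]))
        assert c_cat == coincidence_count(a1, b1) + coincidence_count(a2, b2)


class TestSynchronyTimecourse:
    def _raster(self, trials, w0, w1):
        return AlignedRaster(unit_id="u", event_label="e", window_start=w0,
                             window_end=w1, trials=trials)

    def test_stationary_flat(self):
        rng = np.random.default_rng(4)
        tr_a = [np.sort(rng.uniform(0, 2, 40)) for _ in range(30)]
        tr_b = [np.sort(rng.uniform(0, 2, 40)) for _ in range(30)]
        t, v = synchrony_timecourse(self._raster(tr_a, 0, 2),
                                    self._raster(tr_b, 0, 2))
        v = v[~np.isnan(v)]
        assert v.std() < v.mean()  # no systematic structure

    def test_planted_step_detected(self):
        # Independent 5 sp/s trains become perfectly shared mid-trial; the
        # pooled sliding-window strength must rise after the change point.
        rng = np.random.default_rng(8)
        tr_a, tr_b = [], []
        for _ in range(10):
            shared = np.sort(rng.uniform(1, 2, 5))
            tr_a.append(np.concatenate([np.sort(rng.uniform(0, 1, 5)), shared]))
            tr_b.append(np.concatenate([np.sort(rng.uniform(0, 1, 5)), shared]))
        t, v = synchrony_timecourse(self._raster(tr_a, 0, 2),
                                    self._raster(tr_b, 0, 2))
        assert np.nanmean(v[t > 1.1]) > 1.5 * np.nanmean(v[t < 0.9])

    def test_single_window_reduces_to_strength(self):
        a = [np.array([0.010, 0.050])]
        b = [np.array([0.012])]
        t, v = synchrony_timecourse(self._raster(a, 0, 0.1),
                                    self._raster(b, 0, 0.1),
                                    window=0.1, step=0.1)
        assert v[0] == pytest.approx(synchrony_strength(a[0], b[0]))


class TestPSTH:
    def test_rate_arithmetic(self):
        trials = [np.array([0.005])] * 10
        r = AlignedRaster("u", "e", 0.0, 0.05, trials)
        p = psth(r, bin_width=0.010)
        # 10 spikes over 10 trials x 10 ms bin -> 10/(10*0.01) = 100 sp/s
        assert p.rate[0] == pytest.approx(100.0)
        assert p.rate[1:].sum() == 0

    def test_empty_raster_zero(self):
        r = AlignedRaster("u", "e", 0.0, 0.1, [np.array([])] * 5)
        assert psth(r).rate.sum() == 0

    def test_grand_psth_sem(self):
        r = AlignedRaster("u", "e", 0.0, 0.05, [np.array([0.005])] * 10)
        p = psth(r, 0.01)
        g = grand_psth([p, p, p])
        np.testing.assert_allclose(g.sem, 0.0)
        np.testing.assert_allclose(g.rate, p.rate)

    def test_count_conservation(self):
        rng = np.random.default_rng(6)
        trials = [np.sort(rng.uniform(0, 1, rng.integers(0, 20)))
                  for _ in range(15)]
        r = AlignedRaster("u", "e", 0.0, 1.0, trials)
        p = psth(r, 0.02)
        total = sum(len(t) for t in trials)
        assert p.rate.sum() * 0.02 * 15 == pytest.approx(total)


class TestRateChangeQuantification:
    def test_ongoing_arithmetic(self):
        rng = np.random.default_rng(0)
        tr = [np.sort(np.concatenate([rng.uniform(-0.5, 0, 5),
                                      rng.uniform(0.25, 0.75, 10)]))]
        r = AlignedRaster("u", "LED", -0.5, 0.75, tr)
        per, mean = ongoing_rate_change(r)
        assert per[0] == pytest.approx(10.0)

    def test_ongoing_null(self):
        rng = np.random.default_rng(1)
        trials = [np.sort(rng.uniform(-0.5, 0.75, rng.poisson(12.5)))
                  for _ in range(300)]
        r = AlignedRaster("u", "LED", -0.5, 0.75, trials)
        per, mean = ongoing_rate_change(r)
        se = per.std(ddof=1) / np.sqrt(len(per))
        assert abs(mean) < 3 * se

    def test_ongoing_planted_step(self):
        rng = np.random.default_rng(2)
        trials = []
        for _ in range(200):
            pre = rng.uniform(-0.5, 0, rng.poisson(2.5))   # 5 sp/s
            post = rng.uniform(0, 0.75, rng.poisson(11.25))  # 15 sp/s
            trials.append(np.sort(np.concatenate([pre, post])))
        r = AlignedRaster("u", "LED", -0.5, 0.75, trials)
        per, mean = ongoing_rate_change(r)
        se = per.std(ddof=1) / np.sqrt(len(per))
        assert abs(mean - 10.0) < 3 * se

    def test_alternate_window(self):
        tr = [np.array([0.71, 0.72, 0.73])]
        r = AlignedRaster("u", "LED", -0.5, 0.75, tr)
        per, _ = ongoing_rate_change(r, drive_window=(0.70, 0.75),
                                     baseline_window=(-0.05, 0.0))
        assert per[0] == pytest.approx(60.0)

    def test_sensory_arithmetic(self):
        tr = [np.array([0.005, 0.012])]
        r = AlignedRaster("u", "stim", -0.03, 0.03, tr)
        per, mean = sensory_response(r)
        assert per[0] == pytest.approx(2 / 0.03)

    def test_sensory_null(self):
        rng = np.random.default_rng(3)
        trials = [np.sort(rng.uniform(-0.03, 0.03, rng.poisson(1.2)))
                  for _ in range(400)]
        r = AlignedRaster("u", "stim", -0.03, 0.03, trials)
        per, mean = sensory_response(r)
        se = per.std(ddof=1) / np.sqrt(len(per))
        assert abs(mean) < 3 * se

    def test_insufficient_span_rejected(self):
        r = AlignedRaster("u", "LED", -0.1, 0.3, [np.array([])])
        with pytest.raises(ValueError):
            ongoing_rate_change(r)


class TestBurstDetection:
    def test_printed_definition_example(self):
        t = np.array([0.500, 0.5025, 0.5045, 0.900])
        bursts = detect_bursts(SpikeTrain(t, 2.0))
        assert bursts == [(0, 3)]  # the 0.900 spike is not a burst

    def test_silence_precondition(self):
        t = np.array([0.450, 0.500, 0.5025])
        assert detect_bursts(SpikeTrain(t, 2.0)) == []

    def test_start_of_recording_conservative(self):
        t = np.array([0.050, 0.0525])
        assert detect_bursts(SpikeTrain(t, 2.0), t_start=0.0) == []
        assert detect_bursts(SpikeTrain(t, 2.0), t_start=None) == []
        t2 = np.array([0.150, 0.1525])
        assert detect_bursts(SpikeTrain(t2, 2.0), t_start=0.0) == [(0, 2)]

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            # Mix slow background with occasional fast doublets/triplets.
            n = int(rng.integers(0, 40))
            t = np.sort(rng.uniform(0, 5, n))
            pick = rng.random(n) < 0.3
            extra = t[pick] + rng.uniform(0.001, 0.006, size=int(pick.sum()))
            allt = np.unique(np.concatenate([t, extra]))
            got = detect_bursts(allt)
            assert got == brute_force_bursts(list(allt))

    def test_burst_structure_invariants(self):
        rng = np.random.default_rng(23)
        t = np.sort(rng.uniform(0, 10, 100))
        t = np.unique(np.concatenate([t, t[::7] + 0.002]))
        bursts = detect_bursts(t)
        idx = burst_spike_indices(t)
        assert set(idx) <= set(range(len(t)))  # burst spikes subset of spikes
        assert len(idx) == len(set(idx))       # non-overlapping
        for start, count in bursts:
            assert count >= 2
            # all intra-burst ISIs < 4 ms
            assert np.all(np.diff(t[start:start + count]) < 0.004)
            # preceded by >= 100 ms silence
            prev = t[start - 1] if start > 0 else 0.0
            assert t[start] - prev >= 0.1
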