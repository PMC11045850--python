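"""Circuit-model numerics: closed-form checks, refractoriness, ablations,
calibration, and the frozen default parameter table."""

from dataclasses import replace

import numpy as np
import pytest

from ctloop.lif import (
    DEFAULT_SWEEP_GRID,
    LIFNodeParams,
    SynapseParams,
    calibrate_spontaneous,
    default_config,
    run_condition,
    simulate_trial,
    sweep_point_seed,
    sweep_synchrony,
)

# The published model constants, frozen unit-for-unit (µF, µS, mV, s).
REFERENCE_TABLE = {
    "vpm": dict(C_m=0.00029, g_L=0.029, E_L=-70.0, V_threshold=-54.0,
                V_reset=-80.0, t_refractory=0.002),
    "trn": dict(C_m=0.00014, g_L=0.007, E_L=-80.0, V_threshold=-54.0,
                V_reset=-80.0, t_refractory=0.002),
    "CT->VPm": dict(w=1.0, E_rev=0.0, tau_g=0.1, g_max=0.003, delay=0.001),
    "CT->TRN": dict(w=1.0, E_rev=0.0, tau_g=0.1, g_max=0.003, delay=0.001),
    "TRN->VPm": dict(w=0.075, E_rev=-80.0, tau_g=0.01, g_max=1.0, delay=0.001),
    "Spont->VPm": dict(w=0.0129, E_rev=0.0, tau_g=0.01, g_max=1.0, delay=0.001),
    "Spont->TRN": dict(w=0.0057, E_rev=0.0, tau_g=0.01, g_max=1.0, delay=0.001),
}


def quiet_config(**kw):
    """Default circuit with all stochastic inputs silenced."""
    cfg = default_config(**kw)
    return replace(cfg, spont_rate_vpm=0.0, spont_rate_trn=0.0)


class TestParameterFidelity:
    def test_default_config_matches_reference_table(self):
        cfg = default_config()
        for node in ("vpm", "trn"):
            got = getattr(cfg, node)
            for k, v in REFERENCE_TABLE[node].items():
                assert getattr(got, k) == v, (node, k)
        for name in ("CT->VPm", "CT->TRN", "TRN->VPm", "Spont->VPm",
                     "Spont->TRN"):
            syn = cfg.synapses[name]
            for k, v in REFERENCE_TABLE[name].items():
                assert getattr(syn, k) == v, (name, k)
        assert cfg.ct.n_trains == 35
        assert cfg.ct.rate == 2.5

    def test_membrane_time_constants(self):
        cfg = default_config()
        assert cfg.vpm.tau_m == pytest.approx(0.010)
        assert cfg.trn.tau_m == pytest.approx(0.020)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            LIFNodeParams(C_m=0.0, g_L=1.0, E_L=-70, V_threshold=-54,
                          V_reset=-80)
        with pytest.raises(ValueError):
            LIFNodeParams(C_m=1.0, g_L=1.0, E_L=-70, V_threshold=-80,
                          V_reset=-54)  # reset above threshold
        with pytest.raises(ValueError):
            SynapseParams(w=1.0, E_rev=0.0, tau_g=0.0, g_max=1.0)


class TestMembraneNumerics:
    def test_rest_is_fixed_point(self):
        res = simulate_trial(quiet_config(), 0, ct_enabled=False)
        assert res.vpm_spikes.n_spikes == 0
        assert res.trn_spikes.n_spikes == 0
        np.testing.assert_allclose(res.v_vpm, -70.0, atol=1e-9)
        np.testing.assert_allclose(res.v_trn, -80.0, atol=1e-9)

    @pytest.mark.parametrize("node,tau", [("vpm", 0.010), ("trn", 0.020)])
    def test_exponential_relaxation_closed_form(self, node, tau):
        # Input-free node released from V0 relaxes as
        # E_L + (V0 - E_L) exp(-t g_L / C_m), within 0.05 mV over 50 ms.
        cfg = quiet_config()
        params = getattr(cfg, node)
        v0 = params.E_L + 10.0
        # Drive via a fresh sim whose initial V is E_L: emulate release from
        # v0 by integrating the same forward-Euler map explicitly.
        dt = cfg.dt
        n = int(0.050 / dt)
        v = v0
        sim = np.empty(n)
        for i in range(n):
            v = v + dt / params.C_m * (-params.g_L * (v - params.E_L))
            sim[i] = v
        t = dt * (1 + np.arange(n))
        exact = params.E_L + (v0 - params.E_L) * np.exp(-t / tau)
        assert np.max(np.abs(sim - exact)) < 0.05

    def test_single_ct_spike_conductance_jump_and_decay(self):
        # One presynaptic CT spike increments the VPm CT conductance by
        # g_max exactly one delay later, then the conductance decays by the
        # discrete map g <- g(1 - dt/tau) each step.
        cfg = quiet_config(n_trials=1)
        cfg = replace(cfg, ct=replace(cfg.ct, n_trains=1, rate=0.0))
        # Inject a deterministic CT spike by running with a crafted config:
        # use rate high enough for >=1 spike then keep the first only is
        # fiddly; instead drive the Spont synapse deterministically via a
        # single-spike spontaneous train approximation: use the kernel's
        # contract through simulate_trial with a tiny-rate CT and check any
        # realized arrival.
        cfg2 = replace(cfg, ct=replace(cfg.ct, n_trains=1, rate=4.0, seed=3))
        res = simulate_trial(cfg2, 3)
        arrivals = np.concatenate([tr.times for tr in res.ct_trains]) \
            + cfg2.t_baseline + cfg2.synapses["CT->VPm"].delay
        assert arrivals.size >= 1
        g = res.g_vpm["CT->VPm"]
        dt = cfg2.dt
        tau = cfg2.synapses["CT->VPm"].tau_g
        first = arrivals.min()
        i0 = int(np.floor(first / dt + 1e-9))
        assert g[i0 - 1] == pytest.approx(0.0, abs=1e-15)
        assert g[i0] == pytest.approx(0.003, abs=1e-12)
        # decay between events follows (1 - dt/tau)^k
        k = np.arange(1, 50)
        next_arr = np.sort(arrivals)[1] if arrivals.size > 1 else np.inf
        k = k[(i0 + k) * dt < min(next_arr, cfg2.t_total)]
        np.testing.assert_allclose(
            g[i0 + k], 0.003 * (1 - dt / tau) ** k, rtol=1e-9)

    def test_depolarizing_deflection_matches_fine_step_integrator(self):
        # Reference integration at dt/10 of the same arrival sequence.
        cfg = quiet_config(n_trials=1)
        syn = dict(cfg.synapses)
        syn["TRN->VPm"] = replace(syn["TRN->VPm"], w=0.0)  # isolate CT->VPm
        cfg2 = replace(cfg, synapses=syn,
                       ct=replace(cfg.ct, n_trains=1, rate=4.0, seed=5))
        res = simulate_trial(cfg2, 5)
        p = cfg2.vpm
        syn = cfg2.synapses["CT->VPm"]
        arrivals = np.sort(np.concatenate([tr.times for tr in res.ct_trains])
                           + cfg2.t_baseline + syn.delay)
        assert arrivals.size >= 1
        fine = cfg2.dt / 10
        n = int(round(cfg2.t_total / fine))
        v = p.E_L
        g = 0.0
        arr_steps = set(np.floor(arrivals / fine + 1e-9).astype(int))
        v_fine = np.empty(n)
        for i in range(n):
            if i in arr_steps:
                g += syn.g_max
            I = syn.w * (v - syn.E_rev) * g
            v = v + fine / p.C_m * (-p.g_L * (v - p.E_L) - I)
            v_fine[i] = v
            g -= g * fine / syn.tau_g
        # Compare on the coarse grid, on the subthreshold segment only (the
        # reference integrator has no spike/reset mechanism).
        coarse = res.v_vpm
        if res.vpm_spikes.n_spikes:
            stop = int(res.vpm_spikes.times[0] / cfg2.dt) - 5
        else:
            stop = coarse.size
        assert stop > 1000  # a meaningful stretch is compared
        assert np.max(np.abs(coarse[:stop] - v_fine[9::10][:stop])) < 0.15

    def test_nonfinite_state_aborts(self):
        cfg = quiet_config()
        bad = replace(cfg, vpm=replace(cfg.vpm, E_L=float("nan")))
        with pytest.raises(FloatingPointError, match="non-finite"):
            simulate_trial(bad, 1, ct_enabled=False)


class TestSpikingInvariants:
    @pytest.mark.parametrize("shared_prob", [0.0, 1.0])
    def test_refractory_and_reversal_bounds(self, shared_prob):
        cfg = default_config(shared_prob=shared_prob, seed=2, n_trials=5)
        cond = run_condition(cfg, record_traces=True)
        for res in cond.results:
            for spikes in (res.vpm_spikes, res.trn_spikes):
                if spikes.n_spikes > 1:
                    assert np.min(np.diff(spikes.times)) >= 0.002
            assert res.v_vpm.max() <= -54.0 + 1e-9
            assert res.v_vpm.min() >= -80.0 - 1e-6
            assert res.v_trn.min() >= -80.0 - 1e-6
            for g in list(res.g_vpm.values()) + list(res.g_trn.values()):
                assert g.min() >= 0.0

    def test_no_drive_null(self):
        cfg = default_config(seed=4, n_trials=40)
        syn = dict(cfg.synapses)
        syn["CT->VPm"] = replace(syn["CT->VPm"], w=0.0)
        syn["CT->TRN"] = replace(syn["CT->TRN"], w=0.0)
        cond = run_condition(replace(cfg, synapses=syn))
        assert abs(cond.mean_delta_vpm) < 3 * cond.sem_delta_vpm

    def test_excitation_only_never_suppressed(self):
        cfg = default_config(seed=6, n_trials=30)
        syn = dict(cfg.synapses)
        syn["TRN->VPm"] = replace(syn["TRN->VPm"], w=0.0)
        for p in (0.0, 1.0):
            cond = run_condition(replace(
                cfg, synapses=syn, ct=replace(cfg.ct, shared_prob=p)))
            assert cond.mean_delta_vpm >= -3 * cond.sem_delta_vpm


class TestSweep:
    def test_endpoints_reproduce_run_condition(self):
        cfg = default_config(seed=9, n_trials=4)
        pts = sweep_synchrony(cfg, [0.0, 1.0])
        for k, p in enumerate([0.0, 1.0]):
            direct = run_condition(replace(
                cfg, ct=replace(cfg.ct, shared_prob=p),
                seed=sweep_point_seed(cfg.seed, k)))
            np.testing.assert_allclose(pts[k].condition.delta_vpm,
                                       direct.delta_vpm)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_synchrony(default_config(), [])

    def test_realized_ct_synchrony_increases(self):
        cfg = default_config(seed=10, n_trials=10)
        pts = sweep_synchrony(cfg, [0.0, 1.0])
        assert pts[1].ct_strength > pts[0].ct_strength


class TestCalibration:
    def test_self_check_hits_target(self):
        cfg = default_config(seed=13)
        v, t, va, ta = calibrate_spontaneous(
            cfg, target_vpm_rate=6.3, target_trn_rate=10.0,
            tolerance=0.5, n_trials=10)
        assert abs(va - 6.3) <= 0.5
        assert abs(ta - 10.0) <= 0.5

    def test_rate_monotonicity(self):
        from ctloop.lif import _baseline_rate
        cfg = default_config(seed=14)
        r1 = _baseline_rate(cfg, "vpm", 20, 1)
        r2 = _baseline_rate(replace(cfg, spont_rate_vpm=2 * cfg.spont_rate_vpm),
                            "vpm", 20, 1)
        assert r2 > r1

    def test_infinite_tolerance_single_iteration(self):
        cfg = default_config(seed=15)
        v, t, va, ta = calibrate_spontaneous(
            cfg, tolerance=np.inf, n_trials=2)
        assert np.isfinite(v) and np.isfinite(t)

    def test_unreachable_target_errors(self):
        cfg = default_config(seed=16)
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_spontaneous(cfg, target_vpm_rate=6.3,
                                  target_trn_rate=10.0, n_trials=2,
                                  rate_bounds=(0.0, 1.0))
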