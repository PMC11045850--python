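"""Reduced leaky integrate-and-fire model of the L6CT -> VPm/TRN loop.

Two conductance-based LIF nodes represent the average VPm and TRN neuron.
Both integrate the same ensemble of 35 excitatory corticothalamic (CT)
Poisson inputs whose firing rate and synchrony are controlled independently
(see :mod:`ctloop.poisson`); each node additionally receives its own noisy
excitatory input for spontaneous spiking, and the TRN node inhibits the VPm
node.  There is no VPm -> TRN feedback (its weight is zero).

Membrane dynamics (per node)::

    C_m dV/dt = -g_L (V - E_L) - sum_j w_j (V - E_j) g_j(t)

Each synapse's conductance g_j is incremented by g_jmax one transmission
delay (1 ms) after each presynaptic spike, and decays every step by
``g_j * dt / tau_j``.  On threshold crossing the node emits a spike, V is
set to V_reset and held there for a 2 ms refractory period during which the
conductances keep evolving but cannot move the membrane.  Integration is
forward Euler at dt = 0.1 ms.

All conductances in microsiemens, capacitances in microfarads, potentials in
millivolts, times in seconds (so currents are in nanoamps and C/g time
constants come out in seconds: tau_m = C_m/g_L = 10 ms for VPm, 20 ms TRN).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .poisson import SharedPoissonConfig, gen_poisson, gen_shared_poisson
from .spike_data import SpikeTrain
from .spike_stats import mean_pairwise_strength

__all__ = [
    "LIFNodeParams",
    "SynapseParams",
    "CircuitConfig",
    "SimResult",
    "ConditionResult",
    "SweepPoint",
    "default_config",
    "simulate_trial",
    "run_condition",
    "sweep_synchrony",
    "calibrate_spontaneous",
    "sweep_point_seed",
]

# Synapse keys of the circuit, in kernel order.
VPM_SYNAPSES = ("CT->VPm", "Spont->VPm", "TRN->VPm")
TRN_SYNAPSES = ("CT->TRN", "Spont->TRN")

#: Default shared-probability grid for synchrony sweeps.  The VPm response is
#: nearly flat below p ~ 0.5 (the TRN-mediated inhibition saturates), so the
#: grid concentrates points where the modulation actually varies, giving
#: roughly uniform coverage of the realized synchrony-strength range.
DEFAULT_SWEEP_GRID = (0.0, 0.6, 0.75, 0.85, 1.0)


@dataclass(frozen=True)
class LIFNodeParams:
    """Membrane constants of one LIF node (Table-of-parameters units)."""
    C_m: float          # µF
    g_L: float          # µS
    E_L: float          # mV
    V_threshold: float  # mV
    V_reset: float      # mV
    t_refractory: float = 0.002  # s

    def __post_init__(self):
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError("C_m and g_L must be > 0")
        if not self.V_reset < self.V_threshold:
            raise ValueError("V_reset must be < V_threshold")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_L, seconds."""
        return self.C_m / self.g_L


@dataclass(frozen=True)
class SynapseParams:
    """One synapse type: weight, reversal, decay constant, per-spike increment."""
    w: float        # dimensionless
    E_rev: float    # mV
    tau_g: float    # s
    g_max: float    # µS per presynaptic spike
    delay: float = 0.001  # s

    def __post_init__(self):
        if self.tau_g <= 0:
            raise ValueError("tau_g must be > 0")
        if self.g_max < 0 or self.w < 0:
            raise ValueError("g_max and w must be >= 0")


@dataclass(frozen=True)
class CircuitConfig:
    vpm: LIFNodeParams
    trn: LIFNodeParams
    synapses: dict          # name -> SynapseParams, keys VPM_SYNAPSES + TRN_SYNAPSES
    ct: SharedPoissonConfig
    spont_rate_vpm: float   # spikes/s of the VPm spontaneous Poisson source
    spont_rate_trn: float
    dt: float = 1e-4        # s
    t_baseline: float = 0.5  # s, spontaneous-only epoch
    t_drive: float = 0.5     # s, CT-drive epoch
    n_trials: int = 50
    seed: int = 0

    def __post_init__(self):
        missing = (set(VPM_SYNAPSES) | set(TRN_SYNAPSES)) - set(self.synapses)
        if missing:
            raise ValueError(f"missing synapses: {sorted(missing)}")
        for name, syn in self.synapses.items():
            if self.dt > syn.delay:
                raise ValueError(f"dt must be <= delay of {name}")
        if self.dt > self.vpm.t_refractory / 2:
            raise ValueError("dt must be <= t_refractory / 2")
        if self.t_baseline <= 0 or self.t_drive <= 0:
            raise ValueError("t_baseline and t_drive must be > 0")

    @property
    def t_total(self) -> float:
        return self.t_baseline + self.t_drive


@dataclass
class SimResult:
    """One trial's output: spikes always; traces when recorded."""
    vpm_spikes: SpikeTrain
    trn_spikes: SpikeTrain
    ct_trains: list | None = None
    t: np.ndarray | None = None          # sample times, s
    v_vpm: np.ndarray | None = None      # mV
    v_trn: np.ndarray | None = None
    g_vpm: dict | None = None            # synapse name -> µS trace
    g_trn: dict | None = None


@dataclass
class ConditionResult:
    """Per-trial rate changes for one synchrony condition."""
    delta_vpm: np.ndarray    # spikes/s, per trial
    delta_trn: np.ndarray
    mean_delta_vpm: float
    sem_delta_vpm: float
    mean_delta_trn: float
    sem_delta_trn: float
    results: list            # SimResult per trial (traces only if requested)


@dataclass
class SweepPoint:
    shared_prob: float
    condition: ConditionResult
    ct_strength: float       # realized mean pairwise CT synchrony (drive epoch)
    mean_g_exc: float        # trial/time mean of w*g for CT->VPm during drive, µS
    mean_g_inh: float        # same for TRN->VPm


def default_config(shared_prob: float = 0.0, seed: int = 0,
                   n_trials: int = 50, **overrides) -> CircuitConfig:
    """The frozen default parameterization of the circuit.

    Membrane/synapse constants are the published model values; the
    spontaneous-input rates were calibrated once (bisection,
    :func:`calibrate_spontaneous`) to baseline firing of 6.3 spikes/s in VPm
    and 10 spikes/s in TRN and are frozen here.
    """
    cfg = CircuitConfig(
        vpm=LIFNodeParams(C_m=0.00029, g_L=0.029, E_L=-70.0,
                          V_threshold=-54.0, V_reset=-80.0),
        trn=LIFNodeParams(C_m=0.00014, g_L=0.007, E_L=-80.0,
                          V_threshold=-54.0, V_reset=-80.0),
        synapses={
            "CT->VPm": SynapseParams(w=1.0, E_rev=0.0, tau_g=0.1, g_max=0.003),
            "CT->TRN": SynapseParams(w=1.0, E_rev=0.0, tau_g=0.1, g_max=0.003),
            "TRN->VPm": SynapseParams(w=0.075, E_rev=-80.0, tau_g=0.01, g_max=1.0),
            "Spont->VPm": SynapseParams(w=0.0129, E_rev=0.0, tau_g=0.01, g_max=1.0),
            "Spont->TRN": SynapseParams(w=0.0057, E_rev=0.0, tau_g=0.01, g_max=1.0),
        },
        ct=SharedPoissonConfig(n_trains=35, rate=2.5, shared_prob=shared_prob,
                               duration=0.5, seed=seed),
        spont_rate_vpm=CALIBRATED_SPONT_VPM,
        spont_rate_trn=CALIBRATED_SPONT_TRN,
        n_trials=n_trials,
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


# Frozen output of calibrate_spontaneous(default circuit, 6.3 sp/s VPm,
# 10 sp/s TRN); see docs/methods.md.
CALIBRATED_SPONT_VPM = 28.5
CALIBRATED_SPONT_TRN = 35.7


# ---------------------------------------------------------------------------
# Integration kernel
# ---------------------------------------------------------------------------

def _kernel(dt, n_steps, delay_steps, refr_steps,
            Cv, gLv, ELv, Vthv, Vrv,
            Ct_, gLt, ELt, Vtht, Vrt,
            w_v, E_v, tau_v, gmax_v,      # VPm synapses: CT, Spont, TRN-inh
            w_t, E_t, tau_t, gmax_t,      # TRN synapses: CT, Spont
            inc_ct_v, inc_spont_v, inc_ct_t, inc_spont_t):
    """Forward-Euler integration of both nodes; returns traces and spikes."""
    Vv = ELv
    Vt = ELt
    gv = np.zeros(3)
    gt = np.zeros(2)
    refr_v = 0
    refr_t = 0
    trn_queue = np.zeros(n_steps + delay_steps + 1, dtype=np.int64)

    trace_vv = np.empty(n_steps)
    trace_vt = np.empty(n_steps)
    trace_gv = np.empty((3, n_steps))
    trace_gt = np.empty((2, n_steps))
    spikes_v = np.empty(n_steps, dtype=np.int64)
    spikes_t = np.empty(n_steps, dtype=np.int64)
    nsv = 0
    nst = 0

    for i in range(n_steps):
        # Delayed presynaptic arrivals increment the conductances.
        gv[0] += gmax_v[0] * inc_ct_v[i]
        gv[1] += gmax_v[1] * inc_spont_v[i]
        gv[2] += gmax_v[2] * trn_queue[i]
        gt[0] += gmax_t[0] * inc_ct_t[i]
        gt[1] += gmax_t[1] * inc_spont_t[i]

        # TRN membrane first so its spike enters the delay queue this step.
        if refr_t > 0:
            Vt = Vrt
            refr_t -= 1
            trace_vt[i] = Vt
        else:
            Isyn = (w_t[0] * (Vt - E_t[0]) * gt[0]
                    + w_t[1] * (Vt - E_t[1]) * gt[1])
            Vt = Vt + dt / Ct_ * (-gLt * (Vt - ELt) - Isyn)
            if Vt >= Vtht:
                trace_vt[i] = Vtht
                spikes_t[nst] = i
                nst += 1
                trn_queue[i + delay_steps] += 1
                Vt = Vrt
                refr_t = refr_steps
            else:
                trace_vt[i] = Vt

        if refr_v > 0:
            Vv = Vrv
            refr_v -= 1
            trace_vv[i] = Vv
        else:
            Isyn = (w_v[0] * (Vv - E_v[0]) * gv[0]
                    + w_v[1] * (Vv - E_v[1]) * gv[1]
                    + w_v[2] * (Vv - E_v[2]) * gv[2])
            Vv = Vv + dt / Cv * (-gLv * (Vv - ELv) - Isyn)
            if Vv >= Vthv:
                trace_vv[i] = Vthv
                spikes_v[nsv] = i
                nsv += 1
                Vv = Vrv
                refr_v = refr_steps
            else:
                trace_vv[i] = Vv

        for k in range(3):
            trace_gv[k, i] = gv[k]
        for k in range(2):
            trace_gt[k, i] = gt[k]

        # Conductance decay: g <- g - g*dt/tau each step.
        for k in range(3):
            gv[k] -= gv[k] * dt / tau_v[k]
        for k in range(2):
            gt[k] -= gt[k] * dt / tau_t[k]

        if not (np.isfinite(Vv) and np.isfinite(Vt)):
            # Signals divergence; caller raises with diagnostics.
            return (trace_vv, trace_vt, trace_gv, trace_gt,
                    spikes_v[:nsv], spikes_t[:nst], i)

    return (trace_vv, trace_vt, trace_gv, trace_gt,
            spikes_v[:nsv], spikes_t[:nst], -1)


try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _kernel = njit(cache=True)(_kernel)
except ImportError:  # pragma: no cover
    pass


def _arrival_counts(spike_times, offset, delay, dt, n_steps) -> np.ndarray:
    """Per-step presynaptic arrival counts, delay applied and quantized to dt."""
    counts = np.zeros(n_steps, dtype=np.int64)
    if len(spike_times):
        steps = np.floor((np.asarray(spike_times) + offset + delay) / dt + 1e-9).astype(np.int64)
        steps = steps[(steps >= 0) & (steps < n_steps)]
        np.add.at(counts, steps, 1)
    return counts


def simulate_trial(config: CircuitConfig, trial_seed: int,
                   record_traces: bool = True,
                   ct_enabled: bool = True) -> SimResult:
    """Simulate one trial: spontaneous-only baseline then the CT-drive epoch.

    CT input trains are drawn fresh from ``config.ct`` (with ``trial_seed``)
    and start at ``t_baseline``; spontaneous inputs run for the whole trial.
    """
    rng = np.random.default_rng(trial_seed)
    dt = config.dt
    n_steps = int(round(config.t_total / dt))
    delay_steps = int(round(config.synapses["CT->VPm"].delay / dt))
    refr_steps = int(round(config.vpm.t_refractory / dt))

    spont_v = gen_poisson(config.spont_rate_vpm, config.t_total, rng)
    spont_t = gen_poisson(config.spont_rate_trn, config.t_total, rng)
    if ct_enabled and config.ct.rate > 0:
        ct_cfg = replace(config.ct, duration=config.t_drive,
                         seed=int(rng.integers(2 ** 31)))
        ct_trains = gen_shared_poisson(ct_cfg)
        ct_pooled = np.sort(np.concatenate([tr.times for tr in ct_trains]))
    else:
        ct_trains = []
        ct_pooled = np.empty(0)

    syn_v = [config.synapses[k] for k in VPM_SYNAPSES]
    syn_t = [config.synapses[k] for k in TRN_SYNAPSES]

    inc_ct_v = _arrival_counts(ct_pooled, config.t_baseline, syn_v[0].delay, dt, n_steps)
    inc_spont_v = _arrival_counts(spont_v.times, 0.0, syn_v[1].delay, dt, n_steps)
    inc_ct_t = _arrival_counts(ct_pooled, config.t_baseline, syn_t[0].delay, dt, n_steps)
    inc_spont_t = _arrival_counts(spont_t.times, 0.0, syn_t[1].delay, dt, n_steps)

    out = _kernel(
        dt, n_steps, delay_steps, refr_steps,
        config.vpm.C_m, config.vpm.g_L, config.vpm.E_L,
        config.vpm.V_threshold, config.vpm.V_reset,
        config.trn.C_m, config.trn.g_L, config.trn.E_L,
        config.trn.V_threshold, config.trn.V_reset,
        np.array([s.w for s in syn_v]), np.array([s.E_rev for s in syn_v]),
        np.array([s.tau_g for s in syn_v]), np.array([s.g_max for s in syn_v]),
        np.array([s.w for s in syn_t]), np.array([s.E_rev for s in syn_t]),
        np.array([s.tau_g for s in syn_t]), np.array([s.g_max for s in syn_t]),
        inc_ct_v, inc_spont_v, inc_ct_t, inc_spont_t,
    )
    vv, vt, gvt, gtt, sv, st, bad = out
    if bad >= 0:
        raise FloatingPointError(
            f"non-finite membrane potential at t = {bad * dt:.4f} s "
            f"(trial seed {trial_seed})"
        )
    t_total = config.t_total
    res = SimResult(
        vpm_spikes=SpikeTrain(sv * dt, t_total),
        trn_spikes=SpikeTrain(st * dt, t_total),
        ct_trains=ct_trains,
    )
    if record_traces:
        res.t = dt * np.arange(n_steps)
        res.v_vpm = vv
        res.v_trn = vt
        res.g_vpm = {k: gvt[i] for i, k in enumerate(VPM_SYNAPSES)}
        res.g_trn = {k: gtt[i] for i, k in enumerate(TRN_SYNAPSES)}
    return res


def run_condition(config: CircuitConfig, record_traces: bool = False,
                  ct_enabled: bool = True) -> ConditionResult:
    """Run ``config.n_trials`` independent trials of one synchrony condition.

    Per trial, the rate change is (drive-epoch count)/t_drive minus
    (baseline count)/t_baseline for each node; the trial mean +/- sem is the
    condition's summary.
    """
    if config.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    master = np.random.default_rng(config.seed)
    trial_seeds = master.integers(2 ** 31, size=config.n_trials)
    dv, dt_ = [], []
    results = []
    for ts in trial_seeds:
        res = simulate_trial(config, int(ts), record_traces=record_traces,
                             ct_enabled=ct_enabled)
        results.append(res)
        for spikes, acc in ((res.vpm_spikes, dv), (res.trn_spikes, dt_)):
            n_drive = spikes.slice(config.t_baseline, config.t_total).n_spikes
            n_base = spikes.slice(0.0, config.t_baseline).n_spikes
            acc.append(n_drive / config.t_drive - n_base / config.t_baseline)
    dv = np.asarray(dv)
    dt_ = np.asarray(dt_)

    def sem(x):
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.inf

    return ConditionResult(
        delta_vpm=dv, delta_trn=dt_,
        mean_delta_vpm=float(dv.mean()), sem_delta_vpm=sem(dv),
        mean_delta_trn=float(dt_.mean()), sem_delta_trn=sem(dt_),
        results=results,
    )


def sweep_point_seed(base_seed: int, k: int) -> int:
    """Deterministic per-grid-point seed for synchrony sweeps."""
    return int(np.random.SeedSequence([int(base_seed), int(k)]).generate_state(1)[0]
               % (2 ** 31))


def sweep_synchrony(config: CircuitConfig, shared_prob_grid,
                    record_traces: bool = False) -> list:
    """One :func:`run_condition` per shared-probability grid point.

    Grid points use independent, deterministic seeds
    (:func:`sweep_point_seed`), so CT realizations are not shared across
    synchrony conditions.  Each point also reports the realized mean pairwise
    CT synchrony strength and the trial/time-mean effective excitatory
    (CT->VPm) and inhibitory (TRN->VPm) conductances during the drive epoch.
    """
    grid = list(shared_prob_grid)
    if not grid:
        raise ValueError("empty shared_prob grid")
    if any(not 0 <= p <= 1 for p in grid):
        raise ValueError("grid values must be in [0, 1]")
    points = []
    for k, p in enumerate(grid):
        pcfg = replace(config,
                       ct=replace(config.ct, shared_prob=float(p)),
                       seed=sweep_point_seed(config.seed, k))
        cond = run_condition(pcfg, record_traces=True)
        strengths = []
        g_exc = []
        g_inh = []
        i_drive = int(round(config.t_baseline / config.dt))
        for res in cond.results:
            if res.ct_trains and any(tr.n_spikes for tr in res.ct_trains):
                strengths.append(mean_pairwise_strength(res.ct_trains))
            g_exc.append(config.synapses["CT->VPm"].w
                         * res.g_vpm["CT->VPm"][i_drive:].mean())
            g_inh.append(config.synapses["TRN->VPm"].w
                         * res.g_vpm["TRN->VPm"][i_drive:].mean())
            if not record_traces:
                res.t = res.v_vpm = res.v_trn = None
                res.g_vpm = res.g_trn = None
        points.append(SweepPoint(
            shared_prob=float(p), condition=cond,
            ct_strength=float(np.mean(strengths)) if strengths else np.nan,
            mean_g_exc=float(np.mean(g_exc)),
            mean_g_inh=float(np.mean(g_inh)),
        ))
    return points


def _baseline_rate(config: CircuitConfig, node: str, n_trials: int,
                   seed: int) -> float:
    """Monte-Carlo baseline firing rate of one node with CT drive disabled."""
    master = np.random.default_rng(seed)
    counts = []
    for _ in range(n_trials):
        res = simulate_trial(config, int(master.integers(2 ** 31)),
                             record_traces=False, ct_enabled=False)
        spikes = res.vpm_spikes if node == "vpm" else res.trn_spikes
        counts.append(spikes.n_spikes / config.t_total)
    return float(np.mean(counts))


def calibrate_spontaneous(config: CircuitConfig,
                          target_vpm_rate: float = 6.3,
                          target_trn_rate: float = 10.0,
                          tolerance: float = 0.3,
                          n_trials: int = 20,
                          rate_bounds=(0.0, 2000.0),
                          max_iter: int = 40):
    """Bisect the two spontaneous-input rates to hit target baseline firing.

    TRN is calibrated first (it is unaffected by VPm), then VPm with the
    calibrated TRN inhibition live.  CT drive is disabled throughout.
    Returns ``(spont_rate_vpm, spont_rate_trn, achieved_vpm, achieved_trn)``.
    Deterministic under ``config.seed``.
    """
    if target_vpm_rate <= 0 or target_trn_rate <= 0:
        raise ValueError("targets must be > 0")

    def bisect(node: str, target: float, cfg: CircuitConfig, seed: int):
        lo, hi = rate_bounds
        f_lo = _baseline_rate(_with_rate(cfg, node, lo), node, n_trials, seed)
        f_hi = _baseline_rate(_with_rate(cfg, node, hi), node, n_trials, seed)
        if not (f_lo <= target <= f_hi):
            raise ValueError(
                f"target {target} sp/s for {node} unreachable within input-rate "
                f"bounds {rate_bounds}: rate({lo})={f_lo:.2f}, "
                f"rate({hi})={f_hi:.2f}"
            )
        mid = 0.5 * (lo + hi)
        achieved = np.inf
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            achieved = _baseline_rate(_with_rate(cfg, node, mid), node,
                                      n_trials, seed)
            if abs(achieved - target) <= tolerance:
                break
            if achieved < target:
                lo = mid
            else:
                hi = mid
        return mid, achieved

    def _with_rate(cfg, node, r):
        key = "spont_rate_vpm" if node == "vpm" else "spont_rate_trn"
        return replace(cfg, **{key: r})

    trn_rate, trn_ach = bisect("trn", target_trn_rate, config, config.seed + 1)
    cfg2 = replace(config, spont_rate_trn=trn_rate)
    vpm_rate, vpm_ach = bisect("vpm", target_vpm_rate, cfg2, config.seed + 2)
    return vpm_rate, trn_rate, vpm_ach, trn_ach
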