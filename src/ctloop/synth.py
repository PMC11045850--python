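"""Synthetic-recording generator: condition-structured sessions with planted truth.

Emulates the study design the analysis assumes — ramp-and-hold LED trials at
five intensities plus a no-LED condition, brief 5 ms LED pulses for
opto-tagging, punctate whisker stimuli 750 ms after LED onset, and 10 Hz
adapting whisker trains — with known (planted) rate modulation, opto-tag
latency structure, waveform widths, sensory responses and thalamic bursts.
Ground-truth tables are written alongside the recording so every pipeline
stage can be scored against what was actually planted.

The generator draws unit spiking from inhomogeneous Poisson processes whose
rate profile follows the LED waveform (linear ramp over 250 ms, then a hold
at baseline x multiplier).  It makes no attempt to model membrane dynamics,
adaptation beyond the planted train amplitudes, or realistic waveforms
beyond a scalar trough-to-peak time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .poisson import gen_inhomogeneous_poisson
from .spike_data import Recording, SpikeTrain, UnitMeta, write_recording

__all__ = ["SynthConfig", "generate_recording", "ground_truth"]

LED_INTENSITIES = (4.0, 8.0, 16.0, 24.0, 30.0)  # mW/mm^2

# Trial slot layout (seconds within each slot).
SLOT_LEN = 3.0
LED_ONSET_IN_SLOT = 1.0
RAMP_DUR = 0.250
HOLD_DUR = 0.750          # LED stays on through the embedded stimulus
STIM_OFFSET = 0.750       # whisker stimulus relative to LED onset
PULSE_SLOT_LEN = 1.5
ADAPT_SLOT_LEN = 2.5
ADAPT_TRAIN_RATE = 10.0   # Hz, 10 deflections over 1 s
ADAPT_TRAIN_ONSET = 1.0


def _default_multipliers() -> dict:
    """Planted per-intensity rate multipliers for each population.

    VPm carries the V-shaped (suppression-then-enhancement) profile; TRN and
    L6CT increase monotonically; S1 RS/FS are mildly modulated.
    """
    return {
        "L6CT": {4.0: 1.5, 8.0: 2.0, 16.0: 3.0, 24.0: 4.0, 30.0: 5.0},
        "RS": {4.0: 1.1, 8.0: 1.2, 16.0: 1.3, 24.0: 1.4, 30.0: 1.5},
        "FS": {4.0: 1.2, 8.0: 1.4, 16.0: 1.5, 24.0: 1.6, 30.0: 1.7},
        "VPm": {4.0: 0.8, 8.0: 0.7, 16.0: 1.0, 24.0: 1.15, 30.0: 1.3},
        "TRN": {4.0: 1.8, 8.0: 2.0, 16.0: 2.2, 24.0: 2.4, 30.0: 2.5},
    }


@dataclass(frozen=True)
class SynthConfig:
    """Planted structure of a synthetic session."""
    # Desk-scale population sizes.  Paired sign-rank tests need n >= 10 per
    # population for a Bonferroni-corrected p below 0.05 to be attainable
    # (the exact test's smallest two-sided p at n is 2/2^n).
    n_l6ct: int = 6
    n_rs: int = 5
    n_fs: int = 4
    n_vpm: int = 12
    n_trn: int = 5
    #: Baseline firing rates (spikes/s) per population.
    baseline_rates: dict = field(default_factory=lambda: {
        "L6CT": 2.6, "RS": 4.9, "FS": 10.0, "VPm": 6.3, "TRN": 10.0,
    })
    #: population -> {intensity -> rate multiplier during the LED hold}.
    multipliers: dict = field(default_factory=_default_multipliers)
    #: Mean waveform trough-to-peak times (ms) per population.
    tpt_ms: dict = field(default_factory=lambda: {
        "L6CT": 0.70, "RS": 0.65, "FS": 0.30, "VPm": 0.55, "TRN": 0.25,
    })
    n_trials_per_condition: int = 100
    n_pulse_trials: int = 100
    n_adapting_trials: int = 50
    #: Opto-tag latency structure of L6CT units.
    opto_latency: float = 0.003        # s
    opto_jitter: float = 0.0005        # s
    opto_reliability: float = 0.9      # per-pulse spike probability
    #: Planted sensory response: population -> expected extra spikes/stimulus.
    sensory_spikes: dict = field(default_factory=lambda: {
        "L6CT": 0.6, "RS": 0.9, "FS": 1.2, "VPm": 1.5, "TRN": 2.0,
    })
    sensory_latency: float = 0.005     # s
    sensory_decay: float = 0.010       # s, exponential decay of the rate bump
    #: Adapting-train response: fraction of the first-deflection response
    #: retained on the last deflection.
    adapt_fraction: float = 0.6
    burst_prob: float = 0.4            # per VPm LED trial, planted baseline burst
    p_whisker_moving: float = 0.3
    include_noise_profiles: bool = False  # adds noise10/100/500 trial blocks
    primary_whisker: str = "C2"
    seed: int = 0

    def __post_init__(self):
        for pop, m in self.multipliers.items():
            if any(v <= 0 for v in m.values()):
                raise ValueError(f"multipliers must be > 0 ({pop})")
        if any(r < 0 for r in self.baseline_rates.values()):
            raise ValueError("baseline rates must be >= 0")
        if self.n_trials_per_condition < 1:
            raise ValueError("trial counts must be >= 1")


def _populations(cfg: SynthConfig):
    """(unit_id, population, region, layer) for every unit."""
    out = []
    for i in range(cfg.n_l6ct):
        out.append((f"l6ct{i:02d}", "L6CT", "S1", "6"))
    for i in range(cfg.n_rs):
        out.append((f"rs{i:02d}", "RS", "S1", "5"))
    for i in range(cfg.n_fs):
        out.append((f"fs{i:02d}", "FS", "S1", "4"))
    for i in range(cfg.n_vpm):
        out.append((f"vpm{i:02d}", "VPm", "VPm", None))
    for i in range(cfg.n_trn):
        out.append((f"trn{i:02d}", "TRN", "TRN", None))
    return out


def _sensory_profile(amp_spikes, latency, decay, dt, n):
    """Rate bump (spikes/s) integrating to ``amp_spikes`` extra spikes."""
    t = dt * np.arange(n)
    prof = np.zeros(n)
    m = t >= latency
    prof[m] = np.exp(-(t[m] - latency) / decay)
    s = prof.sum() * dt
    return prof * (amp_spikes / s) if s > 0 else prof


def generate_recording(cfg: SynthConfig, directory=None):
    """Generate a synthetic Recording (and write it plus truth tables).

    Returns the in-memory :class:`Recording`; when ``directory`` is given the
    spike_data TSV layout and ``truth_units.tsv`` / ``truth_multipliers.tsv``
    are written there.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 0.001
    units_spec = _populations(cfg)

    # ------------------------------------------------------------------
    # Trial table
    # ------------------------------------------------------------------
    rows = []
    t_cursor = 0.0
    trial_id = 0

    conditions = [(0.0, "none")] + [(i, "ramp_hold") for i in LED_INTENSITIES]
    if cfg.include_noise_profiles:
        conditions += [(16.0, p) for p in ("noise10", "noise100", "noise500")]
    for intensity, profile in conditions:
        for _ in range(cfg.n_trials_per_condition):
            slot = t_cursor
            if profile == "none":
                onset = np.nan
                stim = [slot + LED_ONSET_IN_SLOT + STIM_OFFSET]
            else:
                onset = slot + LED_ONSET_IN_SLOT
                stim = [onset + STIM_OFFSET]
            rows.append({
                "trial_id": f"t{trial_id:04d}",
                "led_intensity": float(intensity),
                "led_profile": profile,
                "led_onset": onset,
                "stim_times": stim,
                "whisker_moving": bool(rng.random() < cfg.p_whisker_moving),
                "trial_kind": "led",
                "whisker": cfg.primary_whisker,
                "slot_start": slot,
            })
            trial_id += 1
            t_cursor += SLOT_LEN

    for _ in range(cfg.n_pulse_trials):
        slot = t_cursor
        rows.append({
            "trial_id": f"t{trial_id:04d}",
            "led_intensity": 30.0,
            "led_profile": "pulse5ms",
            "led_onset": slot + 0.75,
            "stim_times": [],
            "whisker_moving": bool(rng.random() < cfg.p_whisker_moving),
            "trial_kind": "pulse",
            "whisker": "",
            "slot_start": slot,
        })
        trial_id += 1
        t_cursor += PULSE_SLOT_LEN

    for _ in range(cfg.n_adapting_trials):
        slot = t_cursor
        first = slot + ADAPT_TRAIN_ONSET
        stim = [first + k / ADAPT_TRAIN_RATE for k in range(10)]
        rows.append({
            "trial_id": f"t{trial_id:04d}",
            "led_intensity": 0.0,
            "led_profile": "none",
            "led_onset": np.nan,
            "stim_times": stim,
            "whisker_moving": bool(rng.random() < cfg.p_whisker_moving),
            "trial_kind": "adapting",
            "whisker": cfg.primary_whisker,
            "slot_start": slot,
        })
        trial_id += 1
        t_cursor += ADAPT_SLOT_LEN

    duration = t_cursor
    trials = pd.DataFrame(rows)

    # ------------------------------------------------------------------
    # Unit spiking
    # ------------------------------------------------------------------
    units: dict = {}
    spikes: dict = {}
    truth_rows = []
    for uid, pop, region, layer in units_spec:
        base = cfg.baseline_rates[pop]
        tpt = max(0.05, rng.normal(cfg.tpt_ms[pop], 0.02))
        all_times = []
        for row in rows:
            slot = row["slot_start"]
            slot_len = {"led": SLOT_LEN, "pulse": PULSE_SLOT_LEN,
                        "adapting": ADAPT_SLOT_LEN}[row["trial_kind"]]
            n = int(round(slot_len / dt))
            prof = np.full(n, base)
            if row["trial_kind"] == "led" and row["led_profile"] != "none":
                mult = cfg.multipliers[pop].get(row["led_intensity"], 1.0)
                i_on = int(round(LED_ONSET_IN_SLOT / dt))
                i_ramp = int(round((LED_ONSET_IN_SLOT + RAMP_DUR) / dt))
                i_off = int(round((LED_ONSET_IN_SLOT + RAMP_DUR + HOLD_DUR) / dt))
                prof[i_on:i_ramp] = np.linspace(base, base * mult,
                                                i_ramp - i_on, endpoint=False)
                prof[i_ramp:i_off] = base * mult
            # Sensory bumps for whisker stimuli in this slot.
            kind = row["trial_kind"]
            amp0 = cfg.sensory_spikes.get(pop, 0.0)
            if amp0 > 0 and row["stim_times"]:
                stims = row["stim_times"]
                for k, s in enumerate(stims):
                    amp = amp0
                    if kind == "adapting" and len(stims) > 1:
                        frac = 1.0 - (1.0 - cfg.adapt_fraction) * k / (len(stims) - 1)
                        amp = amp0 * frac
                    i0 = int(round((s - slot) / dt))
                    bump = _sensory_profile(amp, cfg.sensory_latency,
                                            cfg.sensory_decay, dt, n - i0)
                    prof[i0:] = prof[i0:] + bump
            tr = gen_inhomogeneous_poisson(prof, dt, slot_len, rng)
            t = tr.times + slot
            # Opto-tagged units spike at short, low-jitter latency per pulse.
            if pop == "L6CT" and kind == "pulse":
                if rng.random() < cfg.opto_reliability:
                    lat = max(0.0005, rng.normal(cfg.opto_latency, cfg.opto_jitter))
                    t = np.concatenate([t, [row["led_onset"] + lat]])
            # Planted thalamic bursts in the pre-LED epoch of VPm trials.
            if pop == "VPm" and kind == "led" and rng.random() < cfg.burst_prob:
                bt = slot + 0.45
                t = t[(t < bt - 0.105) | (t > bt + 0.02)]
                t = np.concatenate([t, bt + np.array([0.0, 0.0025, 0.0048])])
            all_times.append(np.sort(t))
        times = np.concatenate(all_times)
        times = np.sort(times)
        # Enforce strict monotonicity (drop coincidences from concatenation).
        keep = np.concatenate([[True], np.diff(times) > 1e-9])
        st = SpikeTrain(times[keep], duration)
        units[uid] = UnitMeta(unit_id=uid, region=region, tpt_ms=float(tpt),
                              layer=layer)
        spikes[uid] = st
        truth_rows.append({
            "unit_id": uid, "population": pop, "region": region,
            "tpt_ms": float(tpt),
            "baseline_rate": base,
        })

    trials_out = trials.drop(columns=["slot_start"])
    rec = Recording(units=units, spikes=spikes, trials=trials_out,
                    duration=duration)

    if directory is not None:
        write_recording(rec, directory)
        d = os.fspath(directory)
        pd.DataFrame(truth_rows).to_csv(
            os.path.join(d, "truth_units.tsv"), sep="\t", index=False)
        mrows = [
            {"population": pop, "led_intensity": inten, "multiplier": m}
            for pop, mm in cfg.multipliers.items()
            for inten, m in sorted(mm.items())
        ]
        pd.DataFrame(mrows).to_csv(
            os.path.join(d, "truth_multipliers.tsv"), sep="\t", index=False)
    return rec


def ground_truth(directory):
    """Read back the planted truth tables of a generated recording.

    Returns ``(units_df, multipliers_df)``; raises FileNotFoundError when the
    directory lacks the truth files.
    """
    d = os.fspath(directory)
    fu = os.path.join(d, "truth_units.tsv")
    fm = os.path.join(d, "truth_multipliers.tsv")
    for f in (fu, fm):
        if not os.path.exists(f):
            raise FileNotFoundError(f"missing truth table: {f}")
    units = pd.read_csv(fu, sep="\t", dtype={"unit_id": str})
    mult = pd.read_csv(fm, sep="\t")
    return units, mult
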