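"""End-to-end analysis pipeline for a recording directory.

Stages: motion-based trial filtering, unit classification (waveform class,
opto-tagging, stimulus responsiveness, VPm/TRN verification), per-unit
ongoing rate changes and sensory responses per LED condition, population
condition comparisons, pairwise synchrony, and burst tables.  All outputs
are TSV plus a JSON run log; reruns with the same inputs and seed are
byte-identical.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    classify_l6ct,
    classify_rs_fs,
    stimulus_responsive_test,
    vpm_trn_criteria,
    wilcoxon_paired,
)
from .conditions import compare_conditions
from .spike_data import Recording, align_to_events, read_recording
from .spike_stats import detect_bursts, ongoing_rate_change, sensory_response, \
    synchrony_strength

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    labels: pd.DataFrame               # per-unit classification outcome
    ongoing: pd.DataFrame              # per-unit, per-condition ongoing deltas
    comparisons: dict                  # population -> ConditionComparison
    sensory: pd.DataFrame              # per-unit sensory responses (no-LED)
    synchrony: pd.DataFrame            # per-pair strengths
    bursts: pd.DataFrame
    log: dict


def _population(row) -> str | None:
    labels = row["labels"]
    if row["region"] == "VPm":
        return "VPm" if "VPm_verified" in labels else None
    if row["region"] == "TRN":
        return "TRN" if "TRN_verified" in labels else None
    if "L6CT" in labels:
        return "L6CT"
    if "stimulus_responsive" not in labels:
        return None
    if "RS" in labels:
        return "RS"
    if "FS" in labels:
        return "FS"
    return None


def run_pipeline(recording, out_dir=None, seed: int = 0,
                 alpha: float = 0.05) -> PipelineResult:
    """Classify units, quantify LED effects, and compare conditions.

    ``recording`` is a :class:`Recording` or a directory path in the TSV
    exchange layout.  Trials with whisker motion are excluded throughout
    (the per-trial flag also stands in for the peri-stimulus motion rule).
    """
    rec = recording if isinstance(recording, Recording) else read_recording(recording)
    trials = rec.trials
    quiet = trials[~trials["whisker_moving"].astype(bool)]
    kind = quiet["trial_kind"] if "trial_kind" in quiet.columns else \
        pd.Series("led", index=quiet.index)

    led_trials = quiet[(kind == "led")]
    pulse_trials = quiet[quiet["led_profile"] == "pulse5ms"]
    adapt_trials = quiet[(kind == "adapting")] if "trial_kind" in quiet.columns \
        else quiet.iloc[0:0]

    # ------------------------------------------------------------------
    # Classification
    # ------------------------------------------------------------------
    none_trials = led_trials[led_trials["led_profile"] == "none"]
    stim_events = np.array(sorted(
        s for stims in none_trials["stim_times"] for s in stims))

    # A spontaneous epoch for the opto-tag baseline: the window before the
    # first stimulus of the earliest quiet no-LED trial.
    baseline_epoch = None
    if len(none_trials) and stim_events.size:
        s0 = stim_events[0]
        if s0 >= 1.6:
            baseline_epoch = (s0 - 1.70, s0 - 0.10)
        elif s0 >= 1.2:
            baseline_epoch = (max(0.0, s0 - 1.70), s0 - 0.10)

    label_rows = []
    for uid, meta in rec.units.items():
        train = rec.spikes[uid]
        labels = set()
        p_opto = np.nan
        primary = ""
        if meta.region == "S1":
            if meta.tpt_ms is not None:
                wf = classify_rs_fs(meta.tpt_ms)
                if wf != "unclassified":
                    labels.add(wf)
            if len(pulse_trials) >= 2 and baseline_epoch is not None:
                r = align_to_events(train, pulse_trials["led_onset"].to_numpy(float),
                                    0.0, 0.010, unit_id=uid)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cres = classify_l6ct(meta, r, train, baseline_epoch,
                                         seed=seed)
                p_opto = cres.p_values["opto_tag"]
                labels |= cres.labels
            if stim_events.size >= 10:
                r = align_to_events(train, stim_events, -0.050, 0.050, unit_id=uid)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sres = stimulus_responsive_test(r, seed=seed)
                labels |= sres.labels
        else:
            if len(adapt_trials):
                whisker = adapt_trials["whisker"].iloc[0] \
                    if "whisker" in adapt_trials.columns else "PW"
                firsts = np.array([s[0] for s in adapt_trials["stim_times"]])
                lasts = np.array([s[-1] for s in adapt_trials["stim_times"]])
                fr = align_to_events(train, firsts, -0.030, 0.030, unit_id=uid)
                lr = align_to_events(train, lasts, -0.030, 0.030, unit_id=uid)
                vres = vpm_trn_criteria(meta, {whisker: (fr, lr)}, meta.region,
                                        alpha=alpha)
                labels |= vres.labels
                primary = vres.primary_whisker or ""
        label_rows.append({
            "unit_id": uid, "region": meta.region,
            "tpt_ms": np.nan if meta.tpt_ms is None else meta.tpt_ms,
            "layer": meta.layer or "",
            "labels": ";".join(sorted(labels)),
            "opto_p": p_opto, "primary_whisker": primary,
        })
    labels_df = pd.DataFrame(label_rows).sort_values("unit_id").reset_index(drop=True)
    labels_df["labels_set"] = labels_df["labels"].map(
        lambda s: set(s.split(";")) if s else set())

    # ------------------------------------------------------------------
    # Ongoing rate change per unit x condition
    # ------------------------------------------------------------------
    # The no-LED reference uses a virtual onset 750 ms before the embedded
    # stimulus so its quantification windows match the LED conditions.
    cond_onsets = {}
    for _, t in led_trials.iterrows():
        c = float(t["led_intensity"]) if t["led_profile"] != "none" else 0.0
        if t["led_profile"] == "none":
            if not t["stim_times"]:
                continue
            onset = t["stim_times"][0] - 0.750
        else:
            onset = t["led_onset"]
        cond_onsets.setdefault(c, []).append(onset)

    pop_by_unit = {}
    for _, row in labels_df.iterrows():
        pop = _population({"region": row["region"], "labels": row["labels_set"]})
        if pop:
            pop_by_unit[row["unit_id"]] = pop

    ongoing_rows = []
    deltas_by_pop: dict = {}
    for uid, pop in pop_by_unit.items():
        train = rec.spikes[uid]
        for c, onsets in sorted(cond_onsets.items()):
            r = align_to_events(train, onsets, -0.500, 0.750, unit_id=uid)
            per_trial, mean_d = ongoing_rate_change(r)
            base = np.array([np.sum((t >= -0.5) & (t < 0)) for t in r.trials])
            drive = np.array([np.sum((t >= 0.25) & (t < 0.75)) for t in r.trials])
            p_unit = wilcoxon_paired(drive, base)
            ongoing_rows.append({
                "unit_id": uid, "population": pop, "led_intensity": c,
                "n_trials": r.n_trials, "mean_delta": mean_d,
                "p_unit": p_unit,
            })
            deltas_by_pop.setdefault(pop, {}).setdefault(c, {})[uid] = mean_d
    ongoing_df = pd.DataFrame(ongoing_rows)

    comparisons = {}
    n_zero_excluded = 0
    for pop, dd in sorted(deltas_by_pop.items()):
        if len(dd) >= 2 and 0.0 in dd:
            # Units with no spikes anywhere carry no paired information.
            silent = {u for u in dd[0.0] if rec.spikes[u].n_spikes == 0}
            n_zero_excluded += len(silent)
            dd = {c: {u: v for u, v in uu.items() if u not in silent}
                  for c, uu in dd.items()}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    comparisons[pop] = compare_conditions(dd, 0.0)
                except ValueError as e:
                    warnings.warn(f"population {pop}: {e}")

    # ------------------------------------------------------------------
    # Sensory responses (no-LED trials, primary whisker)
    # ------------------------------------------------------------------
    sens_rows = []
    for uid, pop in pop_by_unit.items():
        if stim_events.size:
            r = align_to_events(rec.spikes[uid], stim_events, -0.030, 0.030,
                                unit_id=uid)
            _, mean_d = sensory_response(r)
            sens_rows.append({"unit_id": uid, "population": pop,
                              "mean_evoked_delta": mean_d,
                              "n_trials": r.n_trials})
    sensory_df = pd.DataFrame(sens_rows)

    # ------------------------------------------------------------------
    # Pairwise synchrony within each classified population
    # ------------------------------------------------------------------
    sync_rows = []
    by_pop: dict = {}
    for uid, pop in pop_by_unit.items():
        by_pop.setdefault(pop, []).append(uid)
    for pop, uids in sorted(by_pop.items()):
        uids = sorted(uids)
        for i in range(len(uids)):
            for j in range(i + 1, len(uids)):
                a, b = rec.spikes[uids[i]], rec.spikes[uids[j]]
                if a.n_spikes == 0 and b.n_spikes == 0:
                    continue
                sync_rows.append({
                    "population": pop, "unit_a": uids[i], "unit_b": uids[j],
                    "strength": synchrony_strength(a, b),
                })
    sync_df = pd.DataFrame(sync_rows)

    # ------------------------------------------------------------------
    # Bursts (thalamic signature; computed for VPm and TRN units)
    # ------------------------------------------------------------------
    burst_rows = []
    for uid, meta in rec.units.items():
        if meta.region not in ("VPm", "TRN"):
            continue
        t = rec.spikes[uid].times
        for start, count in detect_bursts(rec.spikes[uid]):
            burst_rows.append({"unit_id": uid, "time_s": t[start],
                               "n_spikes": count})
    bursts_df = pd.DataFrame(burst_rows, columns=["unit_id", "time_s", "n_spikes"])

    log = {
        "package_version": __version__,
        "seed": seed,
        "alpha": alpha,
        "n_units": len(rec.units),
        "n_trials_total": int(len(trials)),
        "n_trials_quiet": int(len(quiet)),
        "populations": {p: len(u) for p, u in sorted(by_pop.items())},
        "conditions": sorted(cond_onsets),
        "n_silent_units_excluded": n_zero_excluded,
    }

    result = PipelineResult(
        labels=labels_df.drop(columns=["labels_set"]),
        ongoing=ongoing_df, comparisons=comparisons,
        sensory=sensory_df, synchrony=sync_df, bursts=bursts_df, log=log,
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        d = os.fspath(out_dir)
        result.labels.to_csv(os.path.join(d, "units_labels.tsv"),
                             sep="\t", index=False, float_format="%.6g")
        ongoing_df.to_csv(os.path.join(d, "ongoing_deltas.tsv"),
                          sep="\t", index=False, float_format="%.6g")
        comp_rows = []
        for pop, comp in sorted(comparisons.items()):
            for c in comp.conditions:
                comp_rows.append({
                    "population": pop, "led_intensity": c,
                    "mean_delta": comp.mean[c], "sem_delta": comp.sem[c],
                    "p_raw": comp.p_raw[c], "p_adjusted": comp.p_adjusted[c],
                    "spearman_rho": comp.spearman_rho,
                    "spearman_p": comp.spearman_p,
                    "n_units": comp.n_units,
                })
        pd.DataFrame(comp_rows).to_csv(
            os.path.join(d, "condition_comparisons.tsv"),
            sep="\t", index=False, float_format="%.6g")
        sensory_df.to_csv(os.path.join(d, "sensory_responses.tsv"),
                          sep="\t", index=False, float_format="%.6g")
        sync_df.to_csv(os.path.join(d, "pair_synchrony.tsv"),
                       sep="\t", index=False, float_format="%.6g")
        bursts_df.to_csv(os.path.join(d, "bursts.tsv"),
                         sep="\t", index=False, float_format="%.6g")
        with open(os.path.join(d, "run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    return result
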