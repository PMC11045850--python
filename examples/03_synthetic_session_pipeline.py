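"""End-to-end analysis of a synthetic optogenetics session.

Generates a recording with planted structure (V-shaped VPm modulation across
LED intensities, opto-tagged L6CT units, sensory responses, bursts), then
runs the full pipeline: motion filtering, classification (waveform class,
opto-tagging, responsiveness, VPm/TRN verification), per-unit rate changes,
and population condition comparisons with Bonferroni-corrected paired tests.
"""

import warnings

from ctloop import SynthConfig, generate_recording, run_pipeline

rec = generate_recording(SynthConfig(seed=0))
print(f"synthetic session: {len(rec.units)} units, {len(rec.trials)} trials, "
      f"{rec.duration:.0f} s")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_pipeline(rec, seed=0)

print("classified populations:", res.log["populations"])
comp = res.comparisons["VPm"]
print("\nVPm ongoing-rate change vs no-LED (mean sp/s, Bonferroni-adjusted p):")
for c in comp.conditions:
    print(f"  {c:>5.0f} mW/mm2: {comp.mean[c]:+6.2f} +/- {comp.sem[c]:.2f}  "
          f"p_adj = {comp.p_adjusted[c]:.4g}")
print(f"rank trend across intensities: rho = {comp.spearman_rho:.3f} "
      f"(p = {comp.spearman_p:.2g})")
print(f"\nbursts detected in thalamic units: {len(res.bursts)}")
print("\nNegative means at low intensities and positive means at high ones "
      "recover the planted suppression-then-enhancement (V-shaped) profile.")
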