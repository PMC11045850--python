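# Methods

## Circuit model

The model reduces the L6CT → VPm/TRN loop to two conductance-based leaky
integrate-and-fire nodes representing the average VPm and TRN neuron. The
membrane equation per node is

    C_m dV/dt = −g_L (V − E_L) − Σ_j w_j (V − E_j) g_j(t)

with capacitance in µF, conductances in µS, potentials in mV and time in
seconds (currents come out in nA, so dV/dt is mV/s and τ_m = C_m/g_L is
10 ms for VPm and 20 ms for TRN). Fixed constants (`ctloop.lif.default_config`,
asserted against a frozen reference table in the tests):

| | VPm | TRN |
|---|---|---|
| C_m (µF) | 0.00029 | 0.00014 |
| g_L (µS) | 0.029 | 0.007 |
| E_L (mV) | −70 | −80 |
| V_threshold (mV) | −54 | −54 |
| V_reset (mV) | −80 | −80 |
| w: CT / TRN→VPm / spont | 1 / 0.075 / 0.0129 | 1 / — / 0.0057 |
| E_rev: CT / TRN→VPm / spont (mV) | 0 / −80 / 0 | 0 / — / 0 |
| τ_g: CT / TRN→VPm / spont (s) | 0.1 / 0.01 / 0.01 | 0.1 / — / 0.01 |
| g_max: CT / TRN→VPm / spont (µS) | 0.003 / 1 / 1 | 0.003 / — / 1 |

There is no VPm→TRN feedback (weight 0), no short-term plasticity, no NMDA
or T-type burst currents, and no intra-TRN recurrence — deliberately: the
model isolates the interplay of the strength and relative timing of
monosynaptic excitation and disynaptic inhibition.

Numerics: forward Euler at dt = 0.1 ms. Synaptic conductances are
incremented g ← g + g_max one 1 ms delay (10 steps) after each presynaptic
spike and decay by the discrete map g ← g − g·dt/τ_g every step; the
"closed form between events" is therefore (1 − dt/τ)^k, which the tests
assert exactly. A spike is recorded at the first sample with V ≥ V_threshold
(the sample is reported at V_threshold), after which V is held at V_reset
for the 2 ms refractory period while conductances keep evolving. The
dt-convergence check (halving dt shifts 50-trial sweep means by well under
one sem) guards the adequacy of the default step.

Trial structure: 0.5 s of spontaneous input only (baseline), then 0.5 s with
the CT ensemble active (drive), mirroring the 500 ms quantification epochs
used for the in-vivo-style analyses. The per-trial effect is
Δrate = count(drive)/0.5 − count(baseline)/0.5; conditions are summarized as
mean ± sem over 50 trials. CT realizations are drawn independently per trial
and per sweep point (seeds derived deterministically from the base seed).

Spontaneous-input rates are not part of the published constant set. They
were calibrated once by bisection (`calibrate_spontaneous`; CT off, the
TRN→VPm synapse live, TRN first then VPm) to baseline firing of 6.3 sp/s in
VPm — the example-neuron baseline the analyses reference — and 10 sp/s in
TRN (a plausible awake baseline; configurable). The calibrated values,
28.5 sp/s (VPm) and 35.7 sp/s (TRN), are frozen as package defaults; a
300-trial check reproduces the targets to ~0.1 sp/s.

## Controlling input synchrony

`gen_shared_poisson` draws, per ensemble member k, one private train I_k and
shares one common train S, all homogeneous Poisson at the target rate. Each
spike of S is copied into member k with probability p; each spike of I_k is
kept with probability 1 − p. The marginal rate is p·r + (1−p)·r = r for all
p, and two members share S-spikes with probability p², so the
exact-coincidence excess grows as p²·r. This graded, per-spike mechanism was
chosen over the alternative whole-train reading (each member is either a
copy of S or fully private), which produces a bimodal rather than graded
synchrony distribution. Copied shared spikes keep identical timestamps
across members (an optional jitter parameter defaults to 0).

Default sweep grid: (0, 0.6, 0.75, 0.85, 1.0). The VPm response is nearly
flat below p ≈ 0.5 — the TRN-mediated inhibitory conductance saturates, so
p = 0 and p = 0.25 differ by ~0.1 sp/s — and a grid uniform in p cannot
rank-order 50-trial condition means reliably. The default grid spaces its
points across the modulation's dynamic range (realized pairwise strengths
~0.03 to ~1.0), which is also the range the time-resolved synchrony measure
reports for real recordings.

## Spike-train statistics

* **Synchrony strength** counts spike pairs with |Δt| ≤ 7.5 ms by exact pair
  enumeration (no lag binning, boundary inclusive) and divides by
  sqrt((N₁² + N₂²)/2). It is symmetric, translation-invariant, 1.0 for
  identical sparse trains, 0 when one train is empty, and an error (0/0)
  when both are.
* **Time-resolved synchrony** pools spikes across trials in a sliding 100 ms
  window stepped by 10 ms before applying the statistic; all-empty windows
  are reported as missing (NaN), not zero. Window and step are parameters —
  no canonical values exist for the published time-resolved panels.
* **PSTHs** use rate = count/(n_trials·bin_width); 10 ms bins by default for
  ongoing epochs, 2 ms recommended for expanded sensory views. Grand PSTHs
  are mean ± sem across units.
* **Ongoing rate change**: count[0.25 s, 0.75 s)/0.5 − count[−0.5 s, 0)/0.5
  per trial relative to LED onset — the drive window starts where the 250 ms
  LED ramp ends. An alternate window (e.g. the last 50 ms of the hold) is a
  parameter.
* **Sensory response**: 30 ms post- minus 30 ms pre-stimulus rate per trial.
* **Bursts**: ≥ 2 spikes with ISIs < 4 ms preceded by ≥ 100 ms without
  spikes (the T-type calcium signature). A candidate burst at the very first
  spike counts only when the epoch start is known to be ≥ 100 ms earlier;
  with an unknown start it is conservatively excluded.

All analysis windows everywhere are half-open [start, end).

## Classification

* **RS/FS**: trough-to-peak time > 0.5 ms → RS, < 0.4 ms → FS; widths in
  [0.4, 0.5] ms are left unclassified and excluded from analysis.
* **Opto-tagging** is a rank-based first-spike-latency test in the spirit of
  the stimulus-associated latency test: first-spike latencies in the 10 ms
  window after each 5 ms pulse are histogrammed at 1 ms resolution and
  compared (Jensen–Shannon divergence, median across windows) against
  latency histograms from 100 equal-length windows drawn from spontaneous
  activity; the p-value is the rank of the pulse window's statistic among
  the baseline windows' leave-one-out statistics (resolution 1/101). Two
  deliberate choices: histograms are conditioned on a spike occurring, and
  add-one smoothed. Conditioning makes temporal *jitter*, not firing rate,
  the tested quantity — a strong responder with 20 ms jitter is not tagged —
  and smoothing prevents the sparse histograms of low-rate units from
  looking spuriously concentrated. A unit is labelled L6CT when p < 0.01
  and it is regular-spiking and in a deep layer (5/6); without a layer label
  the depth gate is skipped with a warning. This is SALT-style, not
  SALT-exact.
* **Stimulus responsiveness** (2-of-3, 50 ms pre/post windows): two-sided
  Wilcoxon signed-rank on counts; zero outside the 95% bootstrap CI of the
  per-trial count difference (1000 percentile resamples, fixed seed); and
  ≥ 3 post-stimulus 10 ms PSTH bins above or ≥ 2 below the 95% bootstrap CI
  of per-bin pre-stimulus activity. Wilcoxon uses the classic
  discard-zero-differences convention, exact for ≤ 25 retained pairs.
* **VPm/TRN verification** from 10 Hz adapting whisker trains: significant
  rate increase (two-sided Wilcoxon, post > pre) to both the first and last
  deflection for some whisker, mean first-spike latency < 15 ms (first) and
  < 20 ms (last) to exclude higher-order-nucleus units, and — VPm only —
  trough-to-peak > 0.3 ms to exclude TRN axonal spikes. The primary whisker
  is chosen by response magnitude, ties broken by latency.

## Condition statistics

Per-unit effects are compared across LED conditions with paired two-sided
Wilcoxon signed-rank tests against a reference condition (no-LED by default,
any condition by argument) with Bonferroni correction over the non-reference
conditions (adjusted p = min(1, p × m), m = 5 for the standard intensity
set). The monotonic-trend statistic is Spearman's rank correlation on pooled
(intensity, per-unit Δ) pairs; a rank trend on the per-condition means is
reported alongside. Units absent from any condition are dropped from the
paired tests with a warning; units with no spikes anywhere are excluded and
counted in the run log.

## Synthetic sessions

`generate_recording` emulates the study design the pipeline assumes: 100
trials per condition for no-LED plus five ramp-and-hold intensities (4, 8,
16, 24, 30 mW/mm²; 250 ms linear ramp then hold, whisker stimulus 750 ms
after LED onset), 100 five-ms pulse trials for opto-tagging, and 50
ten-deflection 10 Hz adapting-train trials. Unit spiking is inhomogeneous
Poisson whose profile follows the LED waveform scaled by planted
per-population multipliers (VPm's default profile is V-shaped: ×0.7 at
8 mW/mm², ×1.3 at 30); L6CT units respond to pulses at 3 ± 0.5 ms latency
with 0.9 reliability; sensory responses are exponential rate bumps (5 ms
latency, 10 ms decay) integrating to a configured spike count; VPm baseline
epochs carry inserted 3-spike bursts; whisker motion is Bernoulli(0.3) per
trial so motion filtering is exercised.

Session sizes are set by power analysis, not convenience: with 12 VPm units
and ~70 quiet trials per condition the planted ×0.7 suppression gives a
per-unit z ≈ 2.2, sufficient for a Bonferroni-corrected exact sign-rank
(whose smallest two-sided p is 2/2ⁿ, so n ≥ 10 units is a structural
requirement for significance at α = 0.05 over 5 comparisons).

What the generator does *not* emulate: membrane dynamics, spike-history
structure beyond the inserted bursts, waveform shapes beyond a scalar
trough-to-peak time, LED-intensity-dependent latency shifts, inter-unit
correlations within a population, and non-stationarity across a session.
Passing tests therefore show that the statistics and classifiers recover
planted rate/latency/label structure under Poisson variability — not that
they are robust to every failure mode of real recordings.

## Known limitations

* The circuit model captures one mechanism (strength vs timing of
  excitation and disynaptic inhibition); quantitative TRN rates are large
  because nothing rate-limits TRN beyond its refractory period.
* The opto-tag test is a reconstruction of the published test's logic, not
  a port; its p-value floor is 1/(n_baseline + 1).
* The burst detector's start-of-epoch convention (conservative exclusion)
  is a choice; bursts straddling analysis-window edges follow the half-open
  rule.
* Exact PSTH bin widths and the time-resolved synchrony windowing behind
  the published figures are unspecified; defaults here are documented
  parameters, not recovered values.
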