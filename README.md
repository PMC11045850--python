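# ctloop

Modeling and analysis of the layer-6 corticothalamic (L6CT) feedback loop
onto the somatosensory thalamus: a reduced leaky integrate-and-fire circuit
model of the L6CT → VPm/TRN pathway with independently controlled input
firing rate and synchrony, together with the spike-train statistics and
unit-classification procedures used to analyze extracellular recordings of
that circuit.

The package is for systems neuroscientists who want to (a) simulate how the
*synchrony* of a corticothalamic input population — at fixed firing rate —
shifts its net effect on thalamic relay (VPm) neurons from suppression to
enhancement, and (b) run the accompanying electrophysiology analyses
(synchrony strength, PSTHs, optogenetic-tagging tests, burst detection,
condition comparisons) on spike-sorted data, or on synthetic sessions with
known planted structure.

## The model

Two conductance-based LIF nodes represent the average VPm and TRN neuron:

    C_m dV/dt = −g_L (V − E_L) − Σ_j w_j (V − E_j) g_j(t)

Each synapse's conductance is incremented by g_max one 1 ms transmission
delay after each presynaptic spike and decays as g ← g − g·dt/τ_g. Both
nodes integrate the same 35 excitatory L6CT Poisson inputs; each receives
its own noisy excitatory input for spontaneous spiking; TRN inhibits VPm
(E_rev = −80 mV); spikes are followed by a 2 ms refractory period in which
conductances evolve but the membrane is clamped at V_reset.

L6CT population synchrony is set by a shared-probability construction: each
input's spikes are drawn from one shared and one private Poisson train
(probability p vs 1 − p per spike), so the marginal rate is identical at
every p while pairwise coincidences grow as p².

Pairwise synchrony is quantified as

    strength = Σ ccg[−7.5 ms … +7.5 ms] / sqrt((N₁² + N₂²)/2),

the coincidence count within ±7.5 ms normalized by the RMS spike count.

## Worked example

```bash
python examples/01_circuit_sweep.py
```

prints (seed 0, 50 trials per point):

```
 shared_prob  ct_strength  mean_delta_vpm  sem_delta_vpm  mean_delta_trn  ...
      0.0000       0.0251         -5.9600         0.5436        205.2800
      0.6000       0.2907         -3.5600         0.6241        177.4000
      0.7500       0.4182         -0.5200         0.8756        154.8000
      0.8500       0.5995          4.4800         1.2785        153.8800
      1.0000       1.0000          5.6800         1.5390        127.6000
suppression at lowest synchrony: True; enhancement at highest: True; positive rank trend (rho=1.000): True
```

At low synchrony the ~6.3 sp/s VPm baseline is suppressed by ~6 sp/s
(TRN-mediated inhibition dominates); at full synchrony it is enhanced by
~6 sp/s, because coincident L6CT spikes drive VPm within the window of
opportunity before the delayed disynaptic inhibition arrives. The other
examples cover the correlated-input generator, the end-to-end synthetic
session pipeline, and the burst/synchrony statistics.

The `ctloop` console script exposes the same drivers
(`ctloop synth | simulate | sweep | analyze`).

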