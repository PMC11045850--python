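"""Correlated Poisson inputs: same firing rate, graded synchrony.

Generates ensembles of spike trains with the shared-probability construction
and shows that the per-train rate stays fixed while the pairwise synchrony
strength (coincidences within +/-7.5 ms, normalized by the RMS spike count)
rises with the shared probability.
"""

import numpy as np

from ctloop import SharedPoissonConfig, gen_shared_poisson
from ctloop.spike_stats import mean_pairwise_strength

print(f"{'shared_p':>9} {'mean rate (sp/s)':>17} {'pairwise strength':>18}")
for p in (0.0, 0.25, 0.5, 0.75, 1.0):
    cfg = SharedPoissonConfig(n_trains=35, rate=2.5, shared_prob=p,
                              duration=300.0, seed=1)
    trains = gen_shared_poisson(cfg)
    rate = np.mean([t.rate for t in trains])
    strength = mean_pairwise_strength(trains)
    print(f"{p:>9.2f} {rate:>17.3f} {strength:>18.4f}")

print()
print("The rate column stays at ~2.5 sp/s for every shared probability; the "
      "strength column rises from the independence baseline (~2*rate*15 ms) "
      "to 1.0 when all trains are copies of one shared train.")
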