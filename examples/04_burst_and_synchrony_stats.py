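"""Spike-train statistics on constructed examples.

Demonstrates the pairwise synchrony strength (exact pair counting within
+/-7.5 ms, normalized by the RMS spike count) and the thalamic burst
criterion (>= 2 spikes with inter-spike intervals < 4 ms after >= 100 ms of
silence).
"""

import numpy as np

from ctloop import SpikeTrain, detect_bursts, synchrony_strength

# Identical sparse trains: every spike coincides with itself -> strength 1.
t = np.arange(10) * 0.020
print("identical trains:", synchrony_strength(t, t))

# Offset by 5 ms: still within the 7.5 ms coincidence window.
print("5 ms offset:     ", synchrony_strength(t, t + 0.005))

# Offset by 10 ms: outside the window -> 0.
print("10 ms offset:    ", synchrony_strength(t, t + 0.010))

# A burst (3 spikes, ISIs 2.5 and 2.0 ms, after 500 ms of silence) followed
# by a lone spike that is not part of any burst.
train = SpikeTrain(np.array([0.500, 0.5025, 0.5045, 0.900]), 2.0)
print("bursts:", detect_bursts(train),
      " (start index, spike count); the 0.900 s spike is not a burst")
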