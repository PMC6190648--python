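"""A small network in both arithmetic modes, with the validation analytics.

A fully connected 256-neuron network (3:1 excitatory:inhibitory, weights
scaled to the benchmark's per-neuron synaptic load) is run for 500 ms in
Q9.24 fixed point and in double precision from identical initial
conditions, then compared on population synchrony, firing rates and ISI
statistics.
"""

import numpy as np

from hhfx import NetworkConfig, run
from hhfx.analysis import (isi_histogram_correlation, mfr_compare,
                           peak_jitter, population_activity)
from hhfx.fixtures import scaled_weights

depth = 64                         # 4 cores x 64 = 256 neurons
params = scaled_weights(3 * depth, depth, density=1.0)
kw = dict(n_cores=4, depth=depth, density=1.0, duration=500.0, seed=1,
          params=params)

fixed = run(NetworkConfig(mode="fixed", **kw))
ref = run(NetworkConfig(mode="reference", **kw))
print(f"fixed:     {len(fixed.events)} spikes, overflows {fixed.overflow_count}")
print(f"reference: {len(ref.events)} spikes")

act_f = population_activity(fixed.trains())
act_r = population_activity(ref.trains())
print(f"synchrony (peak/mean activity): fixed {act_f.max() / act_f.mean():.1f},"
      f" reference {act_r.max() / act_r.mean():.1f}  (>5 means bursting)")
print(f"first-burst jitter: {peak_jitter(act_f, act_r):.3f} ms")

ma, mb, p = mfr_compare(fixed.trains(), ref.trains())
print(f"mean firing rate: {ma:.2f} vs {mb:.2f} Hz (paired t-test p = {p:.3g})")

for bw in (0.15, 5.0):
    rho = isi_histogram_correlation(fixed.trains(), ref.trains(), bin_width=bw)
    print(f"ISI histogram correlation at {bw} ms bins: {rho:.4f}")
print("At fine bins the two modes' narrow inter-burst ISI peaks sit a few")
print("tenths of a percent apart and decorrelate; at coarse bins the")
print("population structure is identical.")
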