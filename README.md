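# hhfx

A bit-faithful software emulator of a fixed-point, multi-core hardware
architecture for simulating randomly connected networks of Hodgkin-Huxley
neurons — together with a double-precision reference simulator and the
analytics used to judge how much accuracy the hardware shortcuts cost.

It is written for computational neuroscientists and digital designers who
want to study, at the bit level and without a synthesis toolchain, what a
resource-frugal spiking-network accelerator actually computes: how
truncating Q9.24 arithmetic, piecewise-linear gating tables, on-the-fly
permutation-generated connectivity and saturated spike counters perturb the
spike trains of a conductance-based network.

## The model

Each neuron is the standard conductance-based HH benchmark cell
(Traub–Miles kinetics, threshold parameter $V_T = -63$ mV) with exponential
excitatory/inhibitory synapses:

$$C_m \dot v = I_{ext} - \bar g_{Na} m^3 h (v-E_{Na}) - \bar g_K n^4 (v-E_K)
  - \bar g_L (v-E_L) - g_e (v-E_e) - g_i (v-E_i),$$

$$\dot x = \big(x_\infty(v) - x\big)\,\tau_x^{-1}(v)\ \ (x \in \{m,n,h\}),
\qquad \dot g_{e,i} = -g_{e,i}/\tau_{e,i},$$

integrated with explicit Euler at $dt = 2^{-7}$ ms so that every
multiplication by $dt$ is an arithmetic right shift.  When a presynaptic
neuron fires, a fixed weight ($w_e$ or $w_i$) is added to the corresponding
conductance of its targets.  The emulated machine:

* carries $v, g_e, g_i$ in Q9.24 (33-bit words, range $[-256, 256)$,
  ulp $2^{-24}$) and stores $m, n, h$ in a reduced Q2.24 format — one
  177-bit memory word per neuron;
* evaluates $x_\infty$ and $\tau_x^{-1}$ from least-squares piecewise-linear
  tables over equal $2^k$ mV segments, addressed by high-order bits of the
  voltage word;
* streams each connectivity row from a density-exact seed bit-vector
  advanced by a fixed single-$N$-cycle permutation (no stored matrix), with
  one seed per core bank;
* counts presynaptic spikes in AND(spike vector, connectivity row) either
  exactly or with a two-level `(k:b]` saturated counter.

## Worked example

```python
from hhfx import run_single_neuron
from hhfx.analysis import isi_stats, relative_isi_error
from hhfx.gating import BASE_STEPS, build_tables

ref = run_single_neuron(duration=2500.0)                       # double precision
fix = run_single_neuron(duration=2500.0, mode="fixed",
                        tables=build_tables(BASE_STEPS))       # Q9.24 + PWL
_, isi_ref = isi_stats(ref, 2500.0)
_, isi_fix = isi_stats(fix, 2500.0)
print(isi_ref, isi_fix, relative_isi_error(isi_ref, isi_fix))
```

prints

```
72.404052734375 72.58392137096774 0.24842343736284836
```

i.e. the isolated benchmark cell fires tonically with a steady-state
interspike interval of 72.404 ms, and the full fixed-point datapath (Q9.24
truncating arithmetic + Base-step gating tables) reproduces that period to
0.25%.  `examples/` contains one short narrative script per capability
(fixed-point arithmetic, table fitting, single-neuron accuracy, streamed
connectivity, saturated counters, network-level comparison), and the `hhfx`
command exposes `fit-pwl`, `run-single`, `run-network`, `analyze` and
`make-fixtures` subcommands for shell use.

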