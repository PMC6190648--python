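# Methods

## Model and constants

The neuron is the conductance-based Hodgkin-Huxley benchmark cell used for
randomly connected network studies: Traub-Miles kinetics shifted by a
threshold parameter, with exponential conductance synapses.  In absolute
units (area 20000 um^2): Cm = 0.2 nF; gNa = 20 uS, gK = 6 uS, gL = 0.01 uS;
ENa = 50, EK = -90, EL = -60, Ee = 0, Ei = -80 mV; tau_e = 5 ms,
tau_i = 10 ms; w_e = 6 nS, w_i = 67 nS; VT = -63 mV; I_ext = 0.  The rate
functions alpha_x, beta_x are the rational closed forms of that kinetics
(`hhfx.gating`); x_inf = alpha/(alpha+beta) and tau^-1 = alpha+beta.  With
these constants the isolated cell is intrinsically tonic: EL sits above the
rest threshold of the kinetics, so it fires regularly with no stimulus —
the double-precision steady-state period at dt = 2^-7 ms is 72.404 ms,
which is the package's primary accuracy yardstick.

A Boltzmann/Gaussian parameterization of the same curves
(`GatingParams`, `fit_boltzmann_gaussian`) is provided as a compact
descriptive form.  It is *not* used in the simulation path: its global
least-squares residuals (1e-3..1e-1) are orders of magnitude larger than
the PWL segment errors, and substituting it shifts the tonic period to
~49 ms.  Everything downstream — the exact reference and the PWL targets —
uses the rational forms, whose PWL error table reproduces the hardware
design's published approximation errors to ~1% (see the gating tests).

## Integration and the fixed-point datapath

Time advances in iterations of dt = 2^-7 ms (128 iterations per ms),
fully explicit: all six state variables are computed from the previous
iteration's values (one global read, then write-back), matching a
read/update/write-back pipeline.  The canonical operation ordering, shared
verbatim by the scalar and vectorized implementations, is:

1. ionic and synaptic currents in nA: `(g * gate) * (E - v)`;
2. their sum `itot`, then `v += (1/Cm) * (itot >> 7)` — the shift is the
   dt multiply, and 1/Cm = 5 is exactly representable;
3. gating: `x += ((x_inf - x) * tau_x^-1) >> 7` with both curve values read
   from the PWL tables;
4. conductance decay: `g -= (g * tau_syn^-1) >> 7`, after the
   presynaptic-count increments `g += count * w`.

This ordering keeps every intermediate inside Q9.24's [-256, 256) range:
measured over the tonic trajectory, I_Na stays in [0, 195] nA, I_K in
[-165, 0] nA, v in [-86, 49] mV.  All multiplications truncate toward
minus infinity (the cheapest hardware rounding; round-to-nearest is
available as an option), and every named register wraps two's-complement
style with a sticky overflow counter.  Overflow is a diagnostic: the
designed runs report zero.

Gating write-back narrows m, n, h to Q2.24 (their values live in [0, 1]),
giving the 177-bit bank word 3x33 + 3x26 reproduced by
`pack_state`/`unpack_state`.

## PWL tables

Each of the six gating curves is fit by least squares on a 256-point
midpoint grid per segment, over equal power-of-two steps on the domain
[-100, 28) mV.  The domain is 2^7 mV wide (so the segment index is a pure
bit-slice of the voltage word) and was chosen because the resulting
worst-case errors reproduce the hardware design's tabulated error matrix
across all three step sets; outside the domain, evaluation clamps to the
boundary segment (the spike peak, ~+48 mV, briefly extrapolates the top
segment of each table — a sub-1e-3 effect included in all results).
The step sets obey the error-balancing constraint
`dm = dn = d(tau_n^-1) = 2 dh = 4 d(tau_h^-1) = 4 d(tau_m^-1)`
(`check_step_constraint`); Base is (2, 2, 1, 0.5, 2, 0.5) mV, Double and
Half scale it by 2 and 1/2.  Coefficients are quantized to Q9.24 by
truncation only when fixed-point tables are materialized.

## Connectivity and counting

Connectivity is defined by a seed row with exactly `round(density * N)`
ones (an exact count, not i.i.d. bits, so density conservation is a hard
invariant) and a uniformly random single-N-cycle permutation; row r of the
matrix is the seed advanced r times (gather convention: output bit j =
input bit perm(j)).  Core c of a C-core, depth-D machine owns rows
cD..cD+D-1 and reloads its seed every iteration, so the row a neuron
consumes depends only on its global id.  The banked simulator exploits
that: it generates each core's D rows once at init by literally iterating
`next_row`, then counts per iteration by gathering the fired columns —
numerically identical to a clock-by-clock walk because all reads use the
previous iteration's spike vector (the one-iteration synaptic delay).  The
independent oracle (`run_flat`) builds the matrix globally and does a
literal packed-bitvector AND + popcount per row; tests require
spike-for-spike identity between the two paths in both counter modes.

Spike counting splits the AND result at the excitatory boundary N_e
(whole banks; partial filling is supported via per-bank active counts) and
either popcounts exactly or applies `(k:b]` saturated windows (consecutive
from each field's bit 0, trailing window partial, cap 2^b - 1).
Saturation only undercounts, and configuration validation refuses the
approximate counter above 20% connectivity density.

## Network experiments

Default geometry mirrors the 4-core example: 4 x 1024 neurons, banks 0-2
excitatory (N_e = 3072), bank 3 inhibitory.  Initial conditions (nowhere
published for this architecture, so fixed here as a package convention):
v uniformly jittered up to 5 mV below EL per neuron, gating at
x_inf(v0), conductances zero; the fixed-point run quantizes the same
floats, so both arithmetic modes start from identical states.  All
randomness (seed row, permutation, jitter) derives from one integer seed.

For networks far from the benchmark operating point (~60 excitatory / ~20
inhibitory presynaptic partners per cell), `scaled_weights` conserves
(expected partners) x weight.  This is what makes the fully connected
scaled-down comparison well-posed: with the unscaled 67 nS inhibitory
weight, a fully connected 512-neuron burst drives g_i to ~8.6 uS and the
inhibitory current past the Q9.24 range (millions of overflow wraps); with
scaling, overflow count is zero and both modes burst synchronously.

Problem sizes in the shipped experiments — 2.5 s single-neuron runs,
150 ms at N = 4096 for the AND-density bound, 500 ms at N = 512-1024 for
the mode comparison — are the package's defaults for desk-scale study;
everything accepts longer durations and larger geometries unchanged.

## Accuracy findings and known discrepancies

* Reference tonic ISI 72.404 ms; Q9.24 + Base tables 72.584 ms (0.25%);
  Half tables 72.581 ms; Double tables 72.727 ms (0.45%).  The period is
  far more sensitive than the nominal table error suggests because the
  interspike drift current is ~0.1 nA against ~5 nA ionic terms: a few
  1e-4 of gating error moves the period by tenths of a percent, and the
  *sign pattern* of the residuals along the subthreshold trajectory, not
  their maximum, decides the shift.  A sensitivity scan (coefficient
  rounding, fit grid density, endpoint interpolation instead of least
  squares, domain edges) moves the Base-table period only within
  72.57-72.59 ms; endpoint interpolation degrades the Double case to
  69.8 ms.  Consequently this emulator does not reproduce the original
  design's reported figure in which doubled steps collapse the period to ~54 ms
  (-25%): that outcome requires the specific unpublished fitted gating
  curves of that design, and no least-squares table over the printed model
  reproduces it.
* The truncated conductance decay has a floor: once g * dt/tau is below
  one ulp the decrement truncates to zero, leaving a small persistent
  conductance (~4e-5 uS for tau_e = 5 ms).  In bursting networks this
  biases the fixed-point inter-burst period by ~1.5% relative to the
  reference — larger than the pooled ISI spread — so ISI histograms binned
  at 0.15 ms share no mass between modes (Pearson r ~ 0) even though at
  5 ms bins r = 0.9999 and spike counts, rates (paired t-test p ~ 1) and
  synchrony agree closely.  Fine-binned histogram correlation is therefore
  reported honestly as near zero at desk scale.
* AND(SV, PV) density: maximum over 150 ms, all neurons, at N = 4096 is
  0.12% (1% connectivity) and 0.20% (20% connectivity) — comfortably below
  the 2% bound that justifies the (64:2] approximate counter.

## What the synthetic experiments do not show

All inputs are synthetic by construction (the architecture needs no data),
but the shipped networks are homogeneous: identical neurons, fixed weights,
no external noise.  Real cortical variability (heterogeneous parameters,
conductance noise, structured topology) would broaden ISI distributions
and likely *raise* fine-binned fixed-vs-reference correlations by masking
the systematic period bias; the desk-scale comparisons here are therefore
conservative about histogram agreement and silent about learning-related
features (the architecture has no plasticity).  Statistical quality of the
permutation-generated connectivity is deliberately out of scope: it is
weaker than a modern PRNG and only its density-conservation and
cycle-length properties are asserted.
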