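"""One explicit-Euler step of the six-variable conductance-based HH neuron.

State: membrane voltage v (mV), gating variables m, n, h, and excitatory /
inhibitory synaptic conductances g_e, g_i (uS).  Dynamics:

    Cm dv/dt = I_ext - gNa m^3 h (v-ENa) - gK n^4 (v-EK) - gL (v-EL)
               - g_e (v-Ee) - g_i (v-Ei)
    dx/dt    = (x_inf(v) - x) / tau_x(v),    x in {m, n, h}
    dg/dt    = -g / tau_syn

discretized fully explicitly at dt = 2**-7 ms: every new value is computed
from the *old* state (one global read, then write-back), and each firing
presynaptic neuron adds a fixed weight to the corresponding conductance
before the decay step (g_up in the update below).

Two arithmetic modes share one canonical operation ordering:

* reference -- IEEE double precision, exact rational gating functions;
* fixed     -- Q9.24 two's-complement arithmetic with truncation, gating
  curves from piecewise-linear tables, every multiply-by-dt a 7-bit
  arithmetic right shift.

The ionic and synaptic currents are computed in nA as (g * gate) * (E - v)
and summed; the sum is shifted by 7 (the dt multiply) and then scaled by
1/Cm = 5.  This ordering keeps every intermediate inside the Q9.24 dynamic
range [-256, 256) for the model's trajectories (currents stay within about
+-200 nA).  The reference mode mirrors the same association so the two
modes differ only in round-off.

All step functions are polymorphic: python scalars for single-neuron runs,
numpy arrays for whole-population updates.  Scalar and vectorized results
are bit-identical (same expression order, same ufuncs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import gating
from .fxp import (Q9_24, Q2_24, OverflowFlags, quantize_raw, wrap_raw,
                  mul_raw, to_float)
from .gating import PwlTable, build_tables, x_inf

__all__ = [
    "DT", "DT_SHIFT", "NeuronParams", "NeuronState",
    "update_state", "detect_spike", "run_single_neuron", "FixedKernel",
    "reference_step",
]

#: integration step, exactly 2**-7 ms (so x*dt is an arithmetic shift by 7)
DT = 2.0 ** -7
DT_SHIFT = 7


@dataclass(frozen=True)
class NeuronParams:
    """Constants of the conductance-based HH benchmark cell.

    Units: capacitance nF, conductances uS, voltages mV, time ms,
    currents nA.  The defaults are the standard benchmark set (cell area
    20000 um^2); with them the isolated cell fires tonically with no
    external stimulus.
    """

    cm: float = 0.2          # nF
    g_na: float = 20.0       # uS
    g_k: float = 6.0
    g_l: float = 0.01
    e_na: float = 50.0       # mV
    e_k: float = -90.0
    e_l: float = -60.0
    e_e: float = 0.0
    e_i: float = -80.0
    tau_e: float = 5.0       # ms
    tau_i: float = 10.0
    w_e: float = 0.006       # uS added to g_e per presynaptic E spike
    w_i: float = 0.067       # uS added to g_i per presynaptic I spike
    i_ext: float = 0.0       # nA

    def __post_init__(self):
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if min(self.g_na, self.g_k, self.g_l) < 0:
            raise ValueError("conductances must be nonnegative")


@dataclass(frozen=True)
class NeuronState:
    v: float
    m: float
    n: float
    h: float
    g_e: float = 0.0
    g_i: float = 0.0

    @classmethod
    def resting(cls, params: NeuronParams, v: float = -65.0) -> "NeuronState":
        """State at voltage v with gating at steady state, conductances 0."""
        return cls(v, float(x_inf("m", v)), float(x_inf("n", v)),
                   float(x_inf("h", v)))


def reference_step(p: NeuronParams, v, m, n, h, g_e_up, g_i_up):
    """Double-precision Euler step from the old state; returns the new
    (v, m, n, h, g_e, g_i) tuple.  g_e_up/g_i_up are the already-incremented
    conductances (equal to the old ones for an isolated neuron)."""
    i_na = (p.g_na * ((m * m * m) * h)) * (p.e_na - v)
    i_k = (p.g_k * ((n * n) * (n * n))) * (p.e_k - v)
    i_l = p.g_l * (p.e_l - v)
    i_e = g_e_up * (p.e_e - v)
    i_i = g_i_up * (p.e_i - v)
    itot = p.i_ext + i_na + i_k + i_l + i_e + i_i
    v_new = v + (itot * DT) * (1.0 / p.cm)
    am, bm = gating.rate_alpha("m", v), gating.rate_beta("m", v)
    an, bn = gating.rate_alpha("n", v), gating.rate_beta("n", v)
    ah, bh = gating.rate_alpha("h", v), gating.rate_beta("h", v)
    m_new = m + ((am / (am + bm) - m) * (am + bm)) * DT
    n_new = n + ((an / (an + bn) - n) * (an + bn)) * DT
    h_new = h + ((ah / (ah + bh) - h) * (ah + bh)) * DT
    ge_new = g_e_up - (g_e_up * (1.0 / p.tau_e)) * DT
    gi_new = g_i_up - (g_i_up * (1.0 / p.tau_i)) * DT
    return v_new, m_new, n_new, h_new, ge_new, gi_new


class FixedKernel:
    """Quantized constants + raw PWL tables for the Q9.24 datapath.

    Holds everything the fixed-point update needs as raw integers; `step`
    performs one Euler iteration on raw scalars or int64 arrays, wrapping
    each named register into its storage format (Q9.24 for v, g_e, g_i;
    the reduced Q2.24 on gating write-back) and noting overflows on the
    sticky `flags`.
    """

    def __init__(self, params: NeuronParams,
                 tables: Mapping[str, PwlTable] | None = None,
                 rounding: str = "truncate"):
        self.params = params
        self.tables = dict(tables) if tables is not None else build_tables()
        self.rounding = rounding
        self.flags = OverflowFlags()
        q = lambda x: quantize_raw(x, 24, rounding)
        self.GNA, self.GK, self.GL = q(params.g_na), q(params.g_k), q(params.g_l)
        self.ENA, self.EK, self.EL = q(params.e_na), q(params.e_k), q(params.e_l)
        self.EE, self.EI = q(params.e_e), q(params.e_i)
        self.INV_CM = q(1.0 / params.cm)
        self.ITAU_E = q(1.0 / params.tau_e)
        self.ITAU_I = q(1.0 / params.tau_i)
        self.WE, self.WI = q(params.w_e), q(params.w_i)
        self.IEXT = q(params.i_ext)
        # raw coefficient arrays + addressing constants per table
        self._tab = {}
        for name, t in self.tables.items():
            k = int(round(np.log2(t.step)))
            self._tab[name] = (
                np.asarray(quantize_raw(t.a, 24, rounding), dtype=np.int64),
                np.asarray(quantize_raw(t.b, 24, rounding), dtype=np.int64),
                quantize_raw(t.v_lo, 24), 24 + k, t.n_segments)

    def quantize_state(self, s: NeuronState):
        q = lambda x: quantize_raw(x, 24, self.rounding)
        return (q(s.v), q(s.m), q(s.n), q(s.h), q(s.g_e), q(s.g_i))

    def _pwl(self, name: str, v_raw):
        ra, rb, lo_raw, shift, nseg = self._tab[name]
        j = (v_raw - lo_raw) >> shift
        if isinstance(j, np.ndarray):
            j = np.clip(j, 0, nseg - 1)
            return mul_raw(ra[j], v_raw) + rb[j]
        j = min(max(int(j), 0), nseg - 1)
        return mul_raw(int(ra[j]), v_raw) + int(rb[j])

    def step(self, v, m, n, h, g_e_up, g_i_up):
        """One fixed-point Euler iteration on raw values (scalars or
        int64 arrays); returns the six new raw values."""
        w = lambda x: wrap_raw(x, Q9_24, self.flags)
        wg = lambda x: wrap_raw(x, Q2_24, self.flags)
        minf = w(self._pwl("m_inf", v))
        ninf = w(self._pwl("n_inf", v))
        hinf = w(self._pwl("h_inf", v))
        itm = w(self._pwl("inv_tau_m", v))
        itn = w(self._pwl("inv_tau_n", v))
        ith = w(self._pwl("inv_tau_h", v))
        m3h = mul_raw(mul_raw(mul_raw(m, m), m), h)
        nn = mul_raw(n, n)
        n4 = mul_raw(nn, nn)
        i_na = w(mul_raw(mul_raw(self.GNA, m3h), self.ENA - v))
        i_k = w(mul_raw(mul_raw(self.GK, n4), self.EK - v))
        i_l = w(mul_raw(self.GL, self.EL - v))
        i_e = w(mul_raw(g_e_up, self.EE - v))
        i_i = w(mul_raw(g_i_up, self.EI - v))
        itot = w(self.IEXT + i_na + i_k + i_l + i_e + i_i)
        v_new = w(v + mul_raw(self.INV_CM, itot >> DT_SHIFT))
        m_new = wg(m + (mul_raw(minf - m, itm) >> DT_SHIFT))
        n_new = wg(n + (mul_raw(ninf - n, itn) >> DT_SHIFT))
        h_new = wg(h + (mul_raw(hinf - h, ith) >> DT_SHIFT))
        ge_new = w(g_e_up - (mul_raw(g_e_up, self.ITAU_E) >> DT_SHIFT))
        gi_new = w(g_i_up - (mul_raw(g_i_up, self.ITAU_I) >> DT_SHIFT))
        return v_new, m_new, n_new, h_new, ge_new, gi_new


def update_state(s: NeuronState, p: NeuronParams, g_e_up: float,
                 g_i_up: float, mode: str = "reference",
                 kernel: FixedKernel | None = None) -> NeuronState:
    """One Euler step at the NeuronState level.

    In fixed mode the state is quantized to Q9.24, stepped through the
    fixed-point datapath, and returned as the represented real values; pass
    a prebuilt `kernel` to keep tables and overflow flags across calls.
    """
    if mode == "reference":
        return NeuronState(*reference_step(p, s.v, s.m, s.n, s.h,
                                           g_e_up, g_i_up))
    if mode == "fixed":
        kernel = kernel or FixedKernel(p)
        v, m, n, h, _, _ = kernel.quantize_state(s)
        q = lambda x: quantize_raw(x, 24, kernel.rounding)
        out = kernel.step(v, m, n, h, q(g_e_up), q(g_i_up))
        return NeuronState(*(to_float(x) for x in out))
    raise ValueError(f"unknown mode {mode!r}")


def detect_spike(v_old: float, v_new: float, threshold: float = -20.0) -> bool:
    """Rising-edge threshold crossing: v_old below, v_new at or above.

    The strict edge condition counts each action potential exactly once even
    though v stays above threshold for many iterations.
    """
    return bool(v_old < threshold <= v_new)


def run_single_neuron(p: NeuronParams | None = None, duration: float = 2500.0,
                      mode: str = "reference",
                      tables: Mapping[str, PwlTable] | None = None,
                      threshold: float = -20.0, v0: float = -65.0,
                      kernel: FixedKernel | None = None,
                      return_trace: bool = False):
    """Simulate an isolated neuron (g_e_up = g_e_old = 0) for `duration` ms.

    Returns spike times in ms (iteration index times dt); with
    ``return_trace`` also the per-iteration voltage (mV).  The default
    initial state is v0 with gating at steady state, which reaches the tonic
    limit cycle within the first spike period.
    """
    if p is None:
        p = NeuronParams()
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_iter = int(round(duration / DT))
    state0 = NeuronState.resting(p, v0)
    spikes = []
    trace = np.empty(n_iter) if return_trace else None

    if mode == "reference":
        v, m, n, h = state0.v, state0.m, state0.n, state0.h
        ge = gi = 0.0
        for it in range(n_iter):
            v2, m, n, h, ge, gi = reference_step(p, v, m, n, h, ge, gi)
            if v < threshold <= v2:
                spikes.append(it * DT)
            if trace is not None:
                trace[it] = v2
            v = v2
    elif mode == "fixed":
        kern = kernel or FixedKernel(p, tables)
        v, m, n, h, ge, gi = kern.quantize_state(state0)
        thr = quantize_raw(threshold, 24)
        for it in range(n_iter):
            v2, m, n, h, ge, gi = kern.step(v, m, n, h, ge, gi)
            if v < thr <= v2:
                spikes.append(it * DT)
            if trace is not None:
                trace[it] = to_float(v2)
            v = v2
    else:
        raise ValueError(f"unknown mode {mode!r}")

    times = np.asarray(spikes, dtype=float)
    return (times, trace) if return_trace else times
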