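"""Multi-core, banked, iteration-synchronous network simulation.

The machine holds N = n_cores * depth neurons.  Each core owns one memory
bank of `depth` state words and one permutation-vector (PV) register seeded
with its slice of the connectivity stream.  An iteration (one dt = 2**-7 ms
step for the whole network) walks the banks slot by slot: for each slot the
cores, in parallel, read a neuron state, AND the *previous* iteration's
spike vector with their current PV row, count excitatory/inhibitory hits,
bump the synaptic conductances by the fixed weights, run the neuron update,
compare old/new voltage against the spike threshold into a per-core partial
spike buffer, and write the state back.  At the iteration boundary the
partial buffers merge into the next spike vector and every PV register
reloads its seed.

Because every slot reads the same previous spike vector, the slot order is
immaterial and the PV row a neuron sees is a fixed function of its global
id (its row of the connectivity matrix).  The implementation exploits both
facts: each core's `depth` rows are generated once at init by literally
iterating the cyclic permutation from the core seed, and each iteration
updates all neurons as one vectorized batch.  Numbers are identical, bit
for bit, to a clock-by-clock walk -- `run_flat` provides the independent
explicit-matrix oracle (packed-bitvector AND + popcount, no banking) that
the tests compare against.

In fixed arithmetic the bank word is 177 bits: v, g_e, g_i in Q9.24
(3 x 33) and m, n, h narrowed to Q2.24 on write-back (3 x 26);
`pack_state`/`unpack_state` reproduce that layout exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from .connectivity import (SeedVector, CyclePermutation, make_seed,
                           make_cycle_permutation, next_row, build_matrix,
                           split_seeds)
from .fxp import Q9_24, Q2_24, OverflowFlags, quantize_raw, wrap_raw, to_float
from .gating import BASE_STEPS, build_tables, x_inf
from .neuron import DT, NeuronParams, FixedKernel, reference_step
from .spikecount import CounterConfig

__all__ = ["NetworkConfig", "BankedState", "SimulationResult",
           "init_network", "step_iteration", "run", "run_flat",
           "pack_state", "unpack_state", "GATING_WORD_BITS", "STATE_WORD_BITS"]

GATING_WORD_BITS = Q2_24.total_bits          # 26
STATE_WORD_BITS = 3 * Q9_24.total_bits + 3 * GATING_WORD_BITS   # 177


@dataclass
class NetworkConfig:
    """Geometry, connectivity, arithmetic and run length of one simulation."""

    n_cores: int = 4
    depth: int = 1024
    n_e: Optional[int] = None        # default 3N/4 (first 3 of 4 cores)
    density: float = 0.02
    counter: CounterConfig = field(default_factory=CounterConfig)
    mode: str = "reference"          # "reference" | "fixed"
    params: NeuronParams = field(default_factory=NeuronParams)
    steps: Dict[str, float] = field(default_factory=lambda: dict(BASE_STEPS))
    seed: int = 0
    threshold: float = -20.0         # mV, rising-edge spike detection
    duration: float = 150.0          # ms; one ms = 128 iterations
    v_init_jitter: float = 5.0       # mV below E_L, uniform per neuron
    active_per_bank: Optional[List[int]] = None   # partial bank filling
    record_and_density: bool = True
    record_v: Sequence[int] = ()

    def __post_init__(self):
        if self.n_e is None:
            # largest whole number of excitatory banks covering ~3/4 of N
            self.n_e = self.depth * max(1, round(0.75 * self.n_cores))
        if self.n_cores < 1 or self.depth < 1:
            raise ValueError("invalid geometry")
        if not 0 <= self.n_e <= self.n or self.n_e % self.depth:
            raise ValueError("n_e must be a whole number of banks")
        if self.mode not in ("reference", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        self.counter.validate_for_density(self.density)
        if self.active_per_bank is not None:
            if len(self.active_per_bank) != self.n_cores:
                raise ValueError("active_per_bank needs one entry per core")
            if any(not 0 <= a <= self.depth for a in self.active_per_bank):
                raise ValueError("active counts must be in [0, depth]")

    @property
    def n(self) -> int:
        return self.n_cores * self.depth

    @property
    def n_iterations(self) -> int:
        return int(round(self.duration / DT))

    def config_hash(self) -> str:
        d = asdict(self)
        d["record_v"] = list(d["record_v"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class BankedState:
    """Live simulation state: per-neuron variables addressed by
    (core, slot) <-> global id = core*depth + slot."""

    cfg: NetworkConfig
    v: np.ndarray
    m: np.ndarray
    n: np.ndarray
    h: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    sv: np.ndarray                      # previous iteration's spike vector
    seeds: List[SeedVector]             # per-core PV seeds
    perm: CyclePermutation
    rows: np.ndarray                    # (N, N) bool: row i = PV row of neuron i
    kernel: Optional[FixedKernel]       # fixed mode only
    active: np.ndarray                  # bool mask of simulated neurons
    iteration: int = 0
    flags: OverflowFlags = field(default_factory=OverflowFlags)

    def state_of(self, i: int):
        """(v, m, n, h, g_e, g_i) of neuron i as real values."""
        vals = (self.v[i], self.m[i], self.n[i], self.h[i],
                self.g_e[i], self.g_i[i])
        if self.cfg.mode == "fixed":
            return tuple(to_float(int(x)) for x in vals)
        return tuple(float(x) for x in vals)


@dataclass
class SimulationResult:
    """Recorded spike events plus optional traces and diagnostics."""

    events: np.ndarray                  # (n_events, 2) int64: iteration, id
    n: int
    n_e: int
    n_iterations: int
    duration: float
    mode: str
    config_hash: str
    seed: int
    overflow_count: int = 0
    and_density: Optional[np.ndarray] = None   # per-iteration max density
    v_trace: Optional[np.ndarray] = None       # (n_iter, n_recorded) mV
    recorded_ids: Sequence[int] = ()

    @property
    def spike_times(self) -> np.ndarray:
        """Event times in ms."""
        return self.events[:, 0] * DT

    def trains(self):
        """Per-neuron sorted spike-time lists as an analysis SpikeTrainSet."""
        from .analysis import SpikeTrainSet
        trains = [[] for _ in range(self.n)]
        for it, i in self.events:
            trains[int(i)].append(int(it) * DT)
        return SpikeTrainSet([np.asarray(t, dtype=float) for t in trains],
                             self.duration, self.n)

    def event_hash(self) -> str:
        return hashlib.sha256(
            np.ascontiguousarray(self.events, dtype=np.int64).tobytes()
        ).hexdigest()


def _initial_floats(cfg: NetworkConfig, rng: np.random.Generator):
    """Initial conditions: v uniformly jittered below E_L per neuron, gating
    at steady state of that v, conductances zero (the hardware zero-fills
    the g memory)."""
    p = cfg.params
    v0 = p.e_l - rng.uniform(0.0, cfg.v_init_jitter, cfg.n)
    return (v0, np.asarray(x_inf("m", v0)), np.asarray(x_inf("n", v0)),
            np.asarray(x_inf("h", v0)), np.zeros(cfg.n), np.zeros(cfg.n))


def init_network(cfg: NetworkConfig) -> BankedState:
    """Build seeds, permutation, per-core streamed row blocks and the
    initial neuron states.  All randomness comes from cfg.seed."""
    n = cfg.n
    # fixed sub-seed derivation keeps the three draws independent
    seed_vec = make_seed(n, cfg.density, cfg.seed * 3 + 1)
    perm = make_cycle_permutation(n, cfg.seed * 3 + 2)
    rng = np.random.default_rng(cfg.seed * 3 + 3)

    seeds = split_seeds(seed_vec, perm, cfg.n_cores, cfg.depth)
    rows = np.empty((n, n), dtype=bool)
    for c, s in enumerate(seeds):
        row = s.bits
        for d in range(cfg.depth):
            rows[c * cfg.depth + d] = row
            if d < cfg.depth - 1:
                row = next_row(row, perm)

    v0, m0, n0, h0, ge0, gi0 = _initial_floats(cfg, rng)
    kernel = None
    if cfg.mode == "fixed":
        kernel = FixedKernel(cfg.params, build_tables(cfg.steps))
        q = lambda x: np.asarray(quantize_raw(x, 24), dtype=np.int64)
        v0, m0, n0, h0, ge0, gi0 = q(v0), q(m0), q(n0), q(h0), q(ge0), q(gi0)

    active = np.ones(n, dtype=bool)
    if cfg.active_per_bank is not None:
        for c, a in enumerate(cfg.active_per_bank):
            active[c * cfg.depth + a:(c + 1) * cfg.depth] = False

    state = BankedState(cfg, v0, m0, n0, h0, ge0, gi0,
                        sv=np.zeros(n, dtype=bool), seeds=seeds, perm=perm,
                        rows=rows, kernel=kernel, active=active)
    if kernel is not None:
        state.flags = kernel.flags
    return state


def _field_counts(rows: np.ndarray, fired: np.ndarray, offset: int,
                  cfg_counter: CounterConfig, n_neurons: int):
    """Exact and (if configured) saturated counts of fired presynaptic
    neurons in one field, for all postsynaptic neurons at once.

    `fired` holds global column indices inside the field; `offset` is the
    field's first column (windows restart there).
    """
    if len(fired) == 0:
        z = np.zeros(n_neurons, dtype=np.int64)
        return z, z
    exact = rows[:, fired].sum(axis=1, dtype=np.int64)
    if cfg_counter.mode == "exact":
        return exact, exact
    k, cap = cfg_counter.k, cfg_counter.cap
    win = (fired - offset) // k
    approx = np.zeros(n_neurons, dtype=np.int64)
    for w in np.unique(win):
        cw = rows[:, fired[win == w]].sum(axis=1, dtype=np.int64)
        approx += np.minimum(cw, cap)
    return exact, approx


def step_iteration(state: BankedState) -> BankedState:
    """Advance the whole network one iteration (in place).

    Counting uses the previous iteration's spike vector (the one-iteration
    synaptic delay); the new spike vector replaces it at the end.
    """
    cfg = state.cfg
    p = cfg.params
    fired = np.flatnonzero(state.sv)
    fe = fired[fired < cfg.n_e]
    fi = fired[fired >= cfg.n_e]
    ce_exact, ce = _field_counts(state.rows, fe, 0, cfg.counter, cfg.n)
    ci_exact, ci = _field_counts(state.rows, fi, cfg.n_e, cfg.counter, cfg.n)

    if cfg.record_and_density and hasattr(state, "_and_density"):
        state._and_density.append(
            (int(ce_exact.max()) + int(ci_exact.max())) / cfg.n
            if len(fired) else 0.0)

    if cfg.mode == "fixed":
        kern = state.kernel
        geu = state.g_e + ce * kern.WE
        giu = state.g_i + ci * kern.WI
        v_new, m_new, n_new, h_new, ge_new, gi_new = kern.step(
            state.v, state.m, state.n, state.h, geu, giu)
        thr = quantize_raw(cfg.threshold, 24)
    else:
        geu = state.g_e + ce * p.w_e
        giu = state.g_i + ci * p.w_i
        v_new, m_new, n_new, h_new, ge_new, gi_new = reference_step(
            p, state.v, state.m, state.n, state.h, geu, giu)
        thr = cfg.threshold

    sv_new = (state.v < thr) & (v_new >= thr) & state.active
    state.v, state.m, state.n, state.h = v_new, m_new, n_new, h_new
    state.g_e, state.g_i = ge_new, gi_new
    state.sv = sv_new
    state.iteration += 1
    return state


def _run_loop(state: BankedState) -> SimulationResult:
    cfg = state.cfg
    n_iter = cfg.n_iterations
    ev_iters: List[np.ndarray] = []
    ev_ids: List[np.ndarray] = []
    if cfg.record_and_density:
        state._and_density = []
    rec = np.asarray(cfg.record_v, dtype=np.int64)
    v_trace = np.empty((n_iter, len(rec))) if len(rec) else None

    for it in range(n_iter):
        step_iteration(state)
        ids = np.flatnonzero(state.sv)
        if len(ids):
            ev_iters.append(np.full(len(ids), it, dtype=np.int64))
            ev_ids.append(ids.astype(np.int64))
        if v_trace is not None:
            v_trace[it] = (to_float(state.v[rec]) if cfg.mode == "fixed"
                           else state.v[rec])

    events = (np.column_stack([np.concatenate(ev_iters),
                               np.concatenate(ev_ids)])
              if ev_iters else np.zeros((0, 2), dtype=np.int64))
    return SimulationResult(
        events=events, n=cfg.n, n_e=cfg.n_e, n_iterations=n_iter,
        duration=cfg.duration, mode=cfg.mode, config_hash=cfg.config_hash(),
        seed=cfg.seed, overflow_count=state.flags.count,
        and_density=(np.asarray(state._and_density)
                     if cfg.record_and_density else None),
        v_trace=v_trace, recorded_ids=tuple(int(i) for i in rec))


def run(cfg: NetworkConfig) -> SimulationResult:
    """Simulate the banked, streamed-connectivity machine for cfg.duration
    ms (duration * 128 iterations)."""
    if cfg.duration <= 0:
        raise ValueError("duration must be positive")
    return _run_loop(init_network(cfg))


# ---------------------------------------------------------------------------
# flat explicit-matrix oracle
# ---------------------------------------------------------------------------

def _pack_field(mat: np.ndarray, k: int) -> np.ndarray:
    """Pack a bool matrix along axis 1 into bytes, padded to a whole number
    of k-bit windows (zero padding cannot change any count)."""
    n, w = mat.shape
    pad = (-w) % max(k, 8)
    if pad:
        mat = np.concatenate([mat, np.zeros((n, pad), dtype=bool)], axis=1)
    return np.packbits(mat, axis=1)


def run_flat(cfg: NetworkConfig) -> SimulationResult:
    """Non-banked reference simulator: the full connectivity matrix is built
    explicitly once, and every iteration performs a literal bitwise AND of
    each matrix row with the spike vector followed by a (windowed) popcount.
    Independent of the banked streaming path; used as its oracle."""
    if cfg.duration <= 0:
        raise ValueError("duration must be positive")
    state = init_network(cfg)     # same seeds/init; rows replaced below
    seed_vec = make_seed(cfg.n, cfg.density, cfg.seed * 3 + 1)
    mat = build_matrix(seed_vec, state.perm)

    k = cfg.counter.k if cfg.counter.mode == "approximate" else 64
    cap = cfg.counter.cap
    byte_windows = k % 8 == 0
    pe = _pack_field(mat[:, :cfg.n_e], k if byte_windows else 8)
    pi = _pack_field(mat[:, cfg.n_e:], k if byte_windows else 8)
    me, mi = mat[:, :cfg.n_e], mat[:, cfg.n_e:]   # for the non-aligned path
    kb = max(k // 8, 1)

    def field_counts(packed, unpacked, sv_field):
        svp = _pack_field(sv_field[None, :], k if byte_windows else 8)[0]
        sel = packed & svp[None, :]
        per_byte = np.bitwise_count(sel)
        if cfg.counter.mode == "exact":
            c = per_byte.sum(axis=1, dtype=np.int64)
            return c, c
        if byte_windows:
            per_win = per_byte.reshape(len(packed), -1, kb).sum(
                axis=2, dtype=np.int64)
            return (per_win.sum(axis=1),
                    np.minimum(per_win, cap).sum(axis=1))
        # windows not byte-aligned: count on the unpacked bits (small N)
        selb = unpacked & sv_field[None, :]
        pad = (-selb.shape[1]) % k
        if pad:
            selb = np.concatenate(
                [selb, np.zeros((len(selb), pad), dtype=bool)], axis=1)
        per_win = selb.reshape(len(selb), -1, k).sum(axis=2, dtype=np.int64)
        return (per_win.sum(axis=1),
                np.minimum(per_win, cap).sum(axis=1))

    cfg = state.cfg
    p = cfg.params
    n_iter = cfg.n_iterations
    ev_iters, ev_ids = [], []
    and_density = [] if cfg.record_and_density else None
    thr = (quantize_raw(cfg.threshold, 24) if cfg.mode == "fixed"
           else cfg.threshold)
    for it in range(n_iter):
        ce_exact, ce = field_counts(pe, me, state.sv[:cfg.n_e])
        ci_exact, ci = field_counts(pi, mi, state.sv[cfg.n_e:])
        if and_density is not None:
            and_density.append((int(ce_exact.max()) + int(ci_exact.max()))
                               / cfg.n if state.sv.any() else 0.0)
        if cfg.mode == "fixed":
            kern = state.kernel
            geu = state.g_e + ce * kern.WE
            giu = state.g_i + ci * kern.WI
            out = kern.step(state.v, state.m, state.n, state.h, geu, giu)
        else:
            geu = state.g_e + ce * p.w_e
            giu = state.g_i + ci * p.w_i
            out = reference_step(p, state.v, state.m, state.n, state.h,
                                 geu, giu)
        v_new, state.m, state.n, state.h, state.g_e, state.g_i = out
        state.sv = (state.v < thr) & (v_new >= thr) & state.active
        state.v = v_new
        ids = np.flatnonzero(state.sv)
        if len(ids):
            ev_iters.append(np.full(len(ids), it, dtype=np.int64))
            ev_ids.append(ids.astype(np.int64))

    events = (np.column_stack([np.concatenate(ev_iters),
                               np.concatenate(ev_ids)])
              if ev_iters else np.zeros((0, 2), dtype=np.int64))
    return SimulationResult(
        events=events, n=cfg.n, n_e=cfg.n_e, n_iterations=n_iter,
        duration=cfg.duration, mode=cfg.mode, config_hash=cfg.config_hash(),
        seed=cfg.seed, overflow_count=state.flags.count,
        and_density=(np.asarray(and_density) if and_density is not None
                     else None))


# ---------------------------------------------------------------------------
# 177-bit bank word
# ---------------------------------------------------------------------------

def _mask(bits: int) -> int:
    return (1 << bits) - 1


def pack_state(v: int, m: int, n: int, h: int, g_e: int, g_i: int,
               flags: OverflowFlags | None = None) -> int:
    """Pack raw Q9.24 state into the 177-bit memory word.

    Layout, MSB first: v(33) g_e(33) g_i(33) m(26) n(26) h(26).  Gating
    values are narrowed to Q2.24 on the way in; narrowing overflow wraps and
    flags."""
    word = 0
    for raw, bits in ((v, 33), (g_e, 33), (g_i, 33)):
        word = (word << bits) | (wrap_raw(int(raw), Q9_24, flags) & _mask(bits))
    for raw, bits in ((m, 26), (n, 26), (h, 26)):
        word = (word << bits) | (wrap_raw(int(raw), Q2_24, flags) & _mask(bits))
    return word


def _sext(x: int, bits: int) -> int:
    return x - (1 << bits) if x >= (1 << (bits - 1)) else x


def unpack_state(word: int) -> tuple:
    """Inverse of pack_state: (v, m, n, h, g_e, g_i) raw integers."""
    h = _sext(word & _mask(26), 26); word >>= 26
    n = _sext(word & _mask(26), 26); word >>= 26
    m = _sext(word & _mask(26), 26); word >>= 26
    g_i = _sext(word & _mask(33), 33); word >>= 33
    g_e = _sext(word & _mask(33), 33); word >>= 33
    v = _sext(word & _mask(33), 33)
    return v, m, n, h, g_e, g_i
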