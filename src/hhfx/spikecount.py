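"""Presynaptic spike counting: AND-select then exact or approximate popcount.

Each neuron's synaptic update needs the number of its presynaptic partners
that fired in the previous iteration, split into excitatory and inhibitory
contributions.  The selection is a bitwise AND of the global spike vector
(SV) with the neuron's connectivity row (PV); the count is either an exact
population count or the two-level approximate counter: the bits are grouped
into consecutive windows of k, each window feeds a saturated counter that
clamps at 2**b - 1 ("(k:b]" in the hardware notation), and an exact adder
tree sums the window outputs.  Saturation can only undercount, and it never
triggers when each window holds at most 2**b - 1 set bits -- which is
overwhelmingly likely in the sparse operating regime (AND density below 2%
with 64-bit windows).  Fully connected networks must use the exact counter;
configuration validation enforces a density bound for the approximate one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpikeVector", "CounterConfig", "and_select", "exact_count",
           "approx_count", "count_synaptic_inputs"]

#: densities above this bound reject the approximate counter
APPROX_SAFE_DENSITY = 0.2


@dataclass(frozen=True)
class SpikeVector:
    """N firing bits; bits [0, n_e) are excitatory, [n_e, N) inhibitory."""

    bits: np.ndarray
    n_e: int

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))
        if not 0 <= self.n_e <= len(self.bits):
            raise ValueError("n_e must lie in [0, N]")

    @property
    def n(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class CounterConfig:
    """mode 'exact' or 'approximate'; (k:b] window size and saturation width."""

    mode: str = "exact"
    k: int = 64
    b: int = 2

    def __post_init__(self):
        if self.mode not in ("exact", "approximate"):
            raise ValueError(f"unknown counter mode {self.mode!r}")
        if self.k < 1 or self.b < 1:
            raise ValueError("k and b must be >= 1")

    @property
    def cap(self) -> int:
        """Saturation ceiling of one first-level counter."""
        return (1 << self.b) - 1

    def validate_for_density(self, density: float,
                             bound: float = APPROX_SAFE_DENSITY) -> None:
        """Reject the approximate counter outside its safe sparse regime."""
        if self.mode == "approximate" and density > bound:
            raise ValueError(
                f"approximate counters require connection density <= {bound}; "
                f"got {density} (use the exact counter)")


def and_select(sv: SpikeVector, pv: np.ndarray) -> np.ndarray:
    """Bitwise AND of spike and connectivity vectors: the set bits are the
    presynaptic neurons that fired last iteration."""
    pv = np.asarray(pv, dtype=bool)
    if len(pv) != sv.n:
        raise ValueError("length mismatch")
    return sv.bits & pv


def exact_count(bits: np.ndarray) -> int:
    """Population count."""
    return int(np.count_nonzero(np.asarray(bits, dtype=bool)))


def approx_count(bits: np.ndarray, k: int = 64, b: int = 2) -> int:
    """Two-level approximate popcount with (k:b] saturated first level.

    Consecutive windows of k bits (the trailing window may be partial) each
    contribute min(popcount(window), 2**b - 1); the second-level adder is
    exact.  Always <= exact_count, with equality iff no window saturates.
    """
    bits = np.asarray(bits, dtype=bool)
    cap = (1 << b) - 1
    n = len(bits)
    if n == 0:
        return 0
    pad = (-n) % k
    padded = np.concatenate([bits, np.zeros(pad, dtype=bool)]) if pad else bits
    window_counts = padded.reshape(-1, k).sum(axis=1)
    return int(np.minimum(window_counts, cap).sum())


def count_synaptic_inputs(sv: SpikeVector, pv: np.ndarray,
                          cfg: CounterConfig = CounterConfig()) -> tuple:
    """(c_e, c_i): counts over the excitatory and inhibitory fields of
    AND(SV, PV).  The two fields are windowed independently, mirroring the
    separate upper/lower counter instances of the hardware."""
    sel = and_select(sv, pv)
    e_bits, i_bits = sel[:sv.n_e], sel[sv.n_e:]
    if cfg.mode == "exact":
        return exact_count(e_bits), exact_count(i_bits)
    return (approx_count(e_bits, cfg.k, cfg.b),
            approx_count(i_bits, cfg.k, cfg.b))
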