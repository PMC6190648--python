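"""On-the-fly random connectivity from a seed vector and a cyclic permutation.

Instead of storing an N x N binary connectivity matrix, the architecture
stores one N-bit seed row with the desired density and a fixed permutation
of {0..N-1} whose cycle decomposition is a single N-cycle.  Row r of the
matrix is the seed permuted r times; because a permutation preserves the
number of set bits, *every* row has exactly the seed's popcount of ones
(density conservation), and the N-cycle property guarantees the N rows are
the N distinct phases of one orbit.

Row r indexes the postsynaptic neuron; its set columns are that neuron's
presynaptic partners.  In a machine with C cores of depth D (N = C*D), core
c streams rows c*D .. (c+1)*D - 1 from its own seed, which is the global
seed advanced c*D times; at the start of every iteration each core's
register is reloaded from its seed, so the row consumed by a neuron is a
function of the neuron id only.

`build_matrix` is the explicit-matrix oracle the streaming path is tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

__all__ = [
    "SeedVector", "CyclePermutation", "make_seed", "make_cycle_permutation",
    "next_row", "build_matrix", "split_seeds",
    "seed_to_hex", "seed_from_hex", "perm_to_text", "perm_from_text",
]

#: guard for the dense oracle (N**2 bits)
MAX_DENSE_N = 16384


@dataclass(frozen=True)
class SeedVector:
    """Binary row of length N with a target fraction of ones."""

    bits: np.ndarray          # bool, shape (N,)
    density: float

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def n(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return int(np.count_nonzero(self.bits))


@dataclass(frozen=True)
class CyclePermutation:
    """A permutation of {0..N-1} that is a single N-cycle."""

    mapping: np.ndarray       # int64, mapping[j] = image of j

    def __post_init__(self):
        m = np.asarray(self.mapping, dtype=np.int64)
        object.__setattr__(self, "mapping", m)
        n = len(m)
        if sorted(m.tolist()) != list(range(n)):
            raise ValueError("not a permutation")
        # single-cycle check: walk the orbit of 0
        seen = 1
        j = int(m[0])
        while j != 0:
            seen += 1
            if seen > n:
                raise ValueError("not a permutation")
            j = int(m[j])
        if seen != n:
            raise ValueError(f"cycle through 0 has length {seen}, need {n}")

    @property
    def n(self) -> int:
        return len(self.mapping)


def make_seed(n: int, density: float, rng_seed: int) -> SeedVector:
    """Seed row with exactly round(density * n) ones at uniform positions.

    The exact count (rather than i.i.d. Bernoulli bits) makes the density-
    conservation invariant and everything downstream of it deterministic.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    k = int(round(density * n))
    bits = np.zeros(n, dtype=bool)
    if k:
        bits[rng.choice(n, size=k, replace=False)] = True
    return SeedVector(bits, density)


def make_cycle_permutation(n: int, rng_seed: int) -> CyclePermutation:
    """A uniformly random single N-cycle.

    A uniform random ordering (o_0 .. o_{n-1}) defines the cycle
    o_0 -> o_1 -> ... -> o_{n-1} -> o_0; every N-cycle arises from exactly
    n orderings, so the draw is uniform over the (n-1)! N-cycles.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    mapping = np.empty(n, dtype=np.int64)
    mapping[order] = np.roll(order, -1)
    return CyclePermutation(mapping)


def next_row(pv: np.ndarray, perm: CyclePermutation) -> np.ndarray:
    """Advance the permutation-vector register one cycle: gather form,
    output bit j = input bit perm(j)."""
    pv = np.asarray(pv, dtype=bool)
    if len(pv) != perm.n:
        raise ValueError("length mismatch")
    return pv[perm.mapping]


def build_matrix(seed: SeedVector, perm: CyclePermutation) -> np.ndarray:
    """Dense oracle: row 0 is the seed, row r+1 = next_row(row r)."""
    n = seed.n
    if n > MAX_DENSE_N:
        raise ValueError(f"refusing dense matrix for N={n} > {MAX_DENSE_N}")
    if perm.n != n:
        raise ValueError("seed/permutation size mismatch")
    mat = np.empty((n, n), dtype=bool)
    row = seed.bits
    for r in range(n):
        mat[r] = row
        row = row[perm.mapping]
    return mat


def split_seeds(seed: SeedVector, perm: CyclePermutation, n_cores: int,
                depth: int) -> List[SeedVector]:
    """Per-core seeds: core c's seed is the global seed advanced c*depth
    cycles (the first row of its 1/n_cores slice of the matrix)."""
    if n_cores * depth != seed.n:
        raise ValueError("n_cores * depth must equal N")
    out = []
    row = seed.bits
    for c in range(n_cores):
        out.append(SeedVector(row.copy(), seed.density))
        if c < n_cores - 1:
            for _ in range(depth):
                row = row[perm.mapping]
    return out


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def seed_to_hex(seed: SeedVector) -> str:
    """Hex bitstring, bit 0 of the row = least significant bit."""
    val = 0
    for i in np.flatnonzero(seed.bits):
        val |= 1 << int(i)
    width = (seed.n + 3) // 4
    return f"{seed.n}:{seed.density!r}:{val:0{width}x}"

def seed_from_hex(s: str) -> SeedVector:
    n_s, dens, hexes = s.strip().split(":")
    n = int(n_s)
    val = int(hexes, 16)
    bits = np.array([(val >> i) & 1 for i in range(n)], dtype=bool)
    return SeedVector(bits, float(dens))

def perm_to_text(perm: CyclePermutation) -> str:
    return " ".join(str(int(x)) for x in perm.mapping)

def perm_from_text(s: str) -> CyclePermutation:
    return CyclePermutation(np.array([int(x) for x in s.split()], dtype=np.int64))
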