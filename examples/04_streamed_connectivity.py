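"""Connectivity on the fly: one seed row + one cyclic permutation.

Instead of storing an N x N random matrix, the machine stores an N-bit seed
with the target density and advances it through a fixed single-N-cycle
permutation: row r is the seed permuted r times.  Every row then has
exactly the same number of ones, and the explicit matrix is recoverable
row by row.
"""

import numpy as np

from hhfx import build_matrix, make_cycle_permutation, make_seed, next_row, split_seeds

N, density = 64, 0.125
seed = make_seed(N, density, rng_seed=7)
perm = make_cycle_permutation(N, rng_seed=8)
print(f"seed: N={N}, density {density} -> popcount {seed.popcount} "
      f"(= round({density} * {N}))")

mat = build_matrix(seed, perm)
print(f"matrix rows all carry {mat.sum(axis=1).min()}..{mat.sum(axis=1).max()}"
      " ones (density conservation)")
print(f"distinct rows: {len({tuple(r) for r in mat.astype(int)})} of {N}")

row = seed.bits
for r in range(N):
    assert np.array_equal(mat[r], row)
    row = next_row(row, perm)
print("streamed register reproduces every matrix row bit-exactly")

seeds = split_seeds(seed, perm, n_cores=4, depth=16)
assert np.array_equal(seeds[2].bits, mat[32])
print("per-core seeds are the matrix's block-leading rows "
      "(core c starts at row c * depth)")
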