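"""Text interchange for simulation artifacts.

Spike events travel as two-column delimited text (iteration, neuron id)
behind a provenance header (config hash, seed, geometry) so a result file
is self-describing and a rerun can be checked against it.  State traces,
which are dense, go into numpy .npz containers.
"""

from __future__ import annotations

import numpy as np

from .network import SimulationResult

__all__ = ["write_events", "read_events", "write_trace"]


def write_events(result: SimulationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("# hhfx spike events\n")
        fh.write(f"# config_hash={result.config_hash} seed={result.seed} "
                 f"mode={result.mode}\n")
        fh.write(f"# n={result.n} n_e={result.n_e} "
                 f"n_iterations={result.n_iterations} "
                 f"duration_ms={result.duration!r} "
                 f"overflow_count={result.overflow_count}\n")
        fh.write("# iteration\tneuron_id\n")
        for it, i in result.events:
            fh.write(f"{int(it)}\t{int(i)}\n")


def read_events(path) -> SimulationResult:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for kv in line[1:].split():
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        meta[k] = v
                continue
            if line.strip():
                a, b = line.split()
                rows.append((int(a), int(b)))
    events = (np.asarray(rows, dtype=np.int64) if rows
              else np.zeros((0, 2), dtype=np.int64))
    return SimulationResult(
        events=events, n=int(meta["n"]), n_e=int(meta["n_e"]),
        n_iterations=int(meta["n_iterations"]),
        duration=float(meta["duration_ms"]), mode=meta.get("mode", "?"),
        config_hash=meta.get("config_hash", "?"),
        seed=int(meta.get("seed", -1)),
        overflow_count=int(meta.get("overflow_count", 0)))


def write_trace(result: SimulationResult, path) -> None:
    """Dense per-iteration voltage traces as a compressed .npz container."""
    if result.v_trace is None:
        raise ValueError("result has no recorded traces")
    np.savez_compressed(path, v_trace=result.v_trace,
                        recorded_ids=np.asarray(result.recorded_ids),
                        config_hash=result.config_hash)
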