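"""Deterministic toy inputs for tests, demos and benchmarks.

Everything here is generated from an explicit integer seed and small enough
that the exhaustive oracles (explicit matrices, naive counters, formula
re-evaluation) run in milliseconds.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .analysis import SpikeTrainSet
from .network import BankedState, NetworkConfig, init_network
from .spikecount import CounterConfig

__all__ = ["toy_network", "synthetic_trains", "scaled_weights"]


def scaled_weights(n_e: int, n_i: int, density: float):
    """Synaptic weights for a network away from the benchmark operating point.

    The benchmark's fixed weights (w_e = 6 nS, w_i = 67 nS) are tuned for
    ~2% connectivity among 4000 neurons (3:1 E:I), i.e. about 60 excitatory
    and 20 inhibitory presynaptic partners per cell.  Denser or smaller
    networks keep the total synaptic drive -- and the Q9.24 dynamic range --
    by conserving (expected presynaptic partners) x weight:

        w_e' = w_e * 60 / (density * n_e),   w_i' = w_i * 20 / (density * n_i).

    Returns a NeuronParams with the scaled weights.
    """
    from .neuron import NeuronParams
    base = NeuronParams()
    if density * n_e <= 0 or density * n_i <= 0:
        return base
    return NeuronParams(
        w_e=base.w_e * 60.0 / (density * n_e),
        w_i=base.w_i * 20.0 / (density * n_i))


def toy_network(n: int = 16, n_cores: int = 4, density: float = 0.25,
                rng_seed: int = 0, mode: str = "reference",
                duration: float = 10.0,
                counter: CounterConfig | None = None,
                ) -> Tuple[NetworkConfig, BankedState]:
    """A ready-to-run miniature of the banked machine.

    Returns the config and its initialized state; every connectivity row of
    the toy has exactly round(density * n) ones.
    """
    if n % n_cores:
        raise ValueError("n must be divisible by n_cores")
    cfg = NetworkConfig(
        n_cores=n_cores, depth=n // n_cores, density=density,
        counter=counter or CounterConfig("exact"),
        mode=mode, seed=rng_seed, duration=duration)
    return cfg, init_network(cfg)


def synthetic_trains(n: int, rate: float, duration: float, rng_seed: int = 0,
                     kind: str = "regular", delta: float = 2.2,
                     burst_period: float = 100.0, burst_width: float = 2.0):
    """Spike-train sets with known statistics.

    kinds:
      regular      -- every neuron fires at exactly `rate` Hz, period-locked
                      (ISI = 1000/rate ms; first spike one period in).
      poisson      -- independent homogeneous Poisson trains at `rate` Hz.
      burst        -- population bursts every `burst_period` ms; each neuron
                      fires once per burst with +-burst_width/2 ms stagger.
      shifted_copy -- a (burst set, identical set delayed by `delta` ms)
                      pair, for jitter-measurement tests.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(rng_seed)

    if kind == "regular":
        if rate == 0:
            trains = [np.empty(0) for _ in range(n)]
        else:
            period = 1000.0 / rate
            base = np.arange(period, duration + 1e-9, period)
            trains = [base.copy() for _ in range(n)]
        return SpikeTrainSet(trains, duration, n)

    if kind == "poisson":
        trains = []
        lam = rate / 1000.0          # spikes per ms
        for _ in range(n):
            if lam == 0:
                trains.append(np.empty(0))
                continue
            # draw enough exponential gaps to cover the duration
            k = max(10, int(2 * lam * duration + 5 * np.sqrt(lam * duration + 1)))
            gaps = rng.exponential(1.0 / lam, size=k)
            t = np.cumsum(gaps)
            while len(t) and t[-1] < duration:
                more = rng.exponential(1.0 / lam, size=k)
                t = np.concatenate([t, t[-1] + np.cumsum(more)])
            trains.append(t[t < duration])
        return SpikeTrainSet(trains, duration, n)

    if kind in ("burst", "shifted_copy"):
        stagger = rng.uniform(-burst_width / 2, burst_width / 2, size=n)
        burst_times = np.arange(burst_period / 2, duration, burst_period)
        trains = [np.sort(burst_times + stagger[i]) for i in range(n)]
        trains = [t[(t >= 0) & (t < duration)] for t in trains]
        a = SpikeTrainSet(trains, duration, n)
        if kind == "burst":
            return a
        shifted = [t[t + delta < duration] + delta for t in trains]
        b = SpikeTrainSet(shifted, duration, n)
        return a, b

    raise ValueError(f"unknown kind {kind!r}")
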