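"""Banked network orchestration: oracle equivalence, determinism, packing."""

import numpy as np
import pytest

from hhfx.fxp import OverflowFlags, quantize_raw
from hhfx.network import (NetworkConfig, STATE_WORD_BITS, init_network,
                          pack_state, run, run_flat, step_iteration,
                          unpack_state)
from hhfx.neuron import NeuronParams, run_single_neuron
from hhfx.spikecount import CounterConfig
from hhfx.fixtures import toy_network


def test_geometry_and_defaults():
    cfg = NetworkConfig(n_cores=4, depth=1024, duration=1.0)
    assert cfg.n == 4096 and cfg.n_e == 3072
    assert cfg.n_iterations == 128          # 1 ms = 128 iterations
    cfg_small = NetworkConfig(n_cores=1, depth=8, duration=1.0, density=0.5)
    assert cfg_small.n == 8
    with pytest.raises(ValueError):
        NetworkConfig(n_cores=4, depth=16, n_e=20, duration=1.0)  # partial bank
    with pytest.raises(ValueError):
        NetworkConfig(density=0.5, counter=CounterConfig("approximate"),
                      duration=1.0)          # approx counter too dense


def test_init_is_deterministic():
    cfg = NetworkConfig(n_cores=2, depth=16, density=0.25, duration=1.0,
                        seed=3)
    s1, s2 = init_network(cfg), init_network(cfg)
    assert np.array_equal(s1.v, s2.v)
    assert np.array_equal(s1.rows, s2.rows)
    assert np.array_equal(s1.seeds[1].bits, s2.seeds[1].bits)


def test_zero_spike_vector_means_pure_decay():
    cfg = NetworkConfig(n_cores=1, depth=8, density=1.0, duration=1.0,
                        mode="reference", seed=0)
    state = init_network(cfg)
    state.g_e[:] = 0.5
    state.g_i[:] = 0.25
    ge0, gi0 = state.g_e.copy(), state.g_i.copy()
    step_iteration(state)      # sv is all-zero: conductances only decay
    assert np.allclose(state.g_e, ge0 * (1 - 2.0 ** -7 / cfg.params.tau_e))
    assert np.allclose(state.g_i, gi0 * (1 - 2.0 ** -7 / cfg.params.tau_i))


@pytest.mark.parametrize("mode", ["reference", "fixed"])
def test_single_neuron_network_reproduces_isolated_run(mode):
    cfg = NetworkConfig(n_cores=1, depth=1, density=0.0, duration=400.0,
                        mode=mode, v_init_jitter=0.0, seed=1)
    res = run(cfg)
    times = run_single_neuron(duration=400.0, mode=mode,
                              v0=cfg.params.e_l)
    assert np.array_equal(res.spike_times, times)


@pytest.mark.parametrize("mode", ["reference", "fixed"])
@pytest.mark.parametrize("counter", [CounterConfig("exact"),
                                     CounterConfig("approximate", 64, 2)])
def test_banked_equals_flat_oracle_toy(mode, counter):
    cfg = NetworkConfig(n_cores=4, depth=16, density=0.2, duration=250.0,
                        mode=mode, counter=counter, seed=2)
    a, b = run(cfg), run_flat(cfg)
    assert np.array_equal(a.events, b.events)
    assert len(a.events) > 0


def test_banked_equals_flat_with_odd_counter_window():
    # (6:1] counter: windows not byte aligned, slow oracle path
    cfg = NetworkConfig(n_cores=2, depth=16, density=0.15, duration=200.0,
                        mode="fixed", counter=CounterConfig("approximate", 6, 1),
                        seed=4)
    assert np.array_equal(run(cfg).events, run_flat(cfg).events)


def test_run_repeats_bit_identically():
    cfg = NetworkConfig(n_cores=4, depth=16, density=0.25, duration=150.0,
                        mode="fixed", seed=5)
    assert run(cfg).event_hash() == run(cfg).event_hash()


def test_excitation_and_inhibition_touch_separate_conductances():
    cfg = NetworkConfig(n_cores=4, depth=4, density=1.0, duration=1.0,
                        mode="reference", seed=0)
    state = init_network(cfg)
    sv = np.zeros(16, bool)
    sv[2] = True                   # excitatory neuron fired
    state.sv = sv
    gi_before = state.g_i.copy()
    step_iteration(state)
    assert np.all(state.g_e > 0)                  # fully connected: all bumped
    assert np.all(state.g_i <= gi_before + 1e-15)  # inhibition untouched
    state2 = init_network(cfg)
    sv2 = np.zeros(16, bool)
    sv2[13] = True                 # inhibitory neuron (id >= n_e = 12)
    state2.sv = sv2
    step_iteration(state2)
    assert np.all(state2.g_i > 0)
    assert np.all(state2.g_e == 0)


def test_partial_bank_filling_silences_inactive_rows():
    cfg = NetworkConfig(n_cores=2, depth=8, density=0.5, duration=400.0,
                        mode="reference", seed=6,
                        active_per_bank=[8, 4])
    res = run(cfg)
    spiking = set(res.events[:, 1].tolist())
    inactive = set(range(12, 16))
    assert spiking and not (spiking & inactive)


def test_toy_fixture_row_popcounts():
    cfg, state = toy_network(n=16, n_cores=4, density=0.25, rng_seed=0)
    assert state.rows.shape == (16, 16)
    assert np.all(state.rows.sum(axis=1) == 4)    # round(0.25 * 16)


def test_state_word_layout_and_roundtrip(rng):
    assert STATE_WORD_BITS == 3 * 33 + 3 * 26 == 177
    for _ in range(50):
        v, ge, gi = (int(rng.integers(-(1 << 32), 1 << 32)) for _ in range(3))
        m, n, h = (int(rng.integers(-(1 << 25), 1 << 25)) for _ in range(3))
        word = pack_state(v, m, n, h, ge, gi)
        assert word >> 177 == 0
        assert unpack_state(word) == (v, m, n, h, ge, gi)
    # a representable voltage survives exactly
    v60 = quantize_raw(-60.0, 24)
    assert unpack_state(pack_state(v60, 0, 0, 0, 0, 0))[0] == v60


def test_pack_narrowing_overflow_flags():
    flags = OverflowFlags()
    too_big = quantize_raw(3.0, 24)        # outside Q2.24 gating range
    pack_state(0, too_big, 0, 0, 0, 0, flags)
    assert flags.count == 1
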