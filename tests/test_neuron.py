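"""Single-neuron dynamics in both arithmetic modes."""

import numpy as np
import pytest

from hhfx import analysis
from hhfx.fxp import quantize_raw, to_float, mul_raw
from hhfx.gating import inv_tau, rate_alpha, rate_beta, x_inf
from hhfx.neuron import (DT, FixedKernel, NeuronParams, NeuronState,
                         detect_spike, reference_step, run_single_neuron,
                         update_state)


def test_steady_state_is_a_fixed_point_of_gating():
    p = NeuronParams()
    s = NeuronState.resting(p, -65.0)
    out = update_state(s, p, 0.0, 0.0, "reference")
    # gating derivative is zero at x = x_inf(v_old)
    assert out.m == pytest.approx(s.m, abs=1e-15)
    assert out.n == pytest.approx(s.n, abs=1e-15)
    assert out.h == pytest.approx(s.h, abs=1e-15)


def test_reference_step_matches_formula_reevaluation_oracle():
    """Independent symbolic-substitution of the discretized equations."""
    p = NeuronParams()
    v, m, n, h, ge, gi = -52.7, 0.21, 0.35, 0.44, 0.013, 0.031
    out = reference_step(p, v, m, n, h, ge, gi)
    itot = (p.i_ext
            + (p.g_na * ((m * m * m) * h)) * (p.e_na - v)
            + (p.g_k * ((n * n) * (n * n))) * (p.e_k - v)
            + p.g_l * (p.e_l - v)
            + ge * (p.e_e - v) + gi * (p.e_i - v))
    assert out[0] == pytest.approx(v + DT * itot / p.cm, rel=1e-14)
    assert out[1] == pytest.approx(m + DT * (x_inf("m", v) - m) * inv_tau("m", v),
                                   rel=1e-12)
    assert out[4] == pytest.approx(ge * (1 - DT / p.tau_e), rel=1e-12)
    assert out[5] == pytest.approx(gi * (1 - DT / p.tau_i), rel=1e-12)


def test_fixed_step_matches_bigint_reevaluation_oracle(base_tables):
    """Bit-exact check of one fixed-point step against a from-scratch
    big-integer evaluation of the same datapath."""
    p = NeuronParams()
    kern = FixedKernel(p, base_tables)
    s = NeuronState(-52.7, 0.21, 0.35, 0.44, 0.013, 0.031)
    v, m, n, h, ge, gi = kern.quantize_state(s)
    got = kern.step(v, m, n, h, ge, gi)

    def pwl(name, vr):
        t = base_tables[name]
        j = min(max((vr - quantize_raw(t.v_lo, 24))
                    >> (24 + int(np.log2(t.step))), 0), t.n_segments - 1)
        return ((int(t.raw_a[j]) * vr) >> 24) + int(t.raw_b[j])

    mul = lambda a, b: (a * b) >> 24
    m3h = mul(mul(mul(m, m), m), h)
    n4 = mul(mul(n, n), mul(n, n))
    itot = (kern.IEXT
            + mul(mul(kern.GNA, m3h), kern.ENA - v)
            + mul(mul(kern.GK, n4), kern.EK - v)
            + mul(kern.GL, kern.EL - v)
            + mul(ge, kern.EE - v) + mul(gi, kern.EI - v))
    assert got[0] == v + mul(kern.INV_CM, itot >> 7)
    assert got[1] == m + (mul(pwl("m_inf", v) - m, pwl("inv_tau_m", v)) >> 7)
    assert got[3] == h + (mul(pwl("h_inf", v) - h, pwl("inv_tau_h", v)) >> 7)
    assert got[4] == ge - (mul(ge, kern.ITAU_E) >> 7)


def test_scalar_and_vector_fixed_paths_are_bit_identical(base_tables):
    p = NeuronParams()
    kern = FixedKernel(p, base_tables)
    s = NeuronState(-60.0, 0.05, 0.3, 0.6, 0.002, 0.004)
    scalars = kern.quantize_state(s)
    arrays = tuple(np.array([x], dtype=np.int64) for x in scalars)
    out_s = kern.step(*scalars)
    out_a = kern.step(*arrays)
    for a, b in zip(out_s, out_a):
        assert int(a) == int(b[0])


@pytest.mark.parametrize("v_old,v_new,thr,expected", [
    (-60.0, 10.0, -20.0, True),
    (10.0, 20.0, -20.0, False),     # already above: no rising edge
    (-60.0, -60.0, -20.0, False),
    (-20.0, -19.0, -20.0, False),   # must start strictly below threshold
    (-21.0, -20.0, -20.0, True),    # crossing onto the threshold counts
])
def test_detect_spike_rising_edge(v_old, v_new, thr, expected):
    assert detect_spike(v_old, v_new, thr) is expected


def test_tonic_regime_is_regular_and_matches_printed_period():
    times = run_single_neuron(duration=1000.0)
    isis, mean_isi = analysis.isi_stats(times, 1000.0)
    assert len(times) >= 12
    # regular (tonic) spiking: steady-state ISIs constant to within one dt
    tail = isis[len(isis) // 2:]
    assert tail.max() - tail.min() <= 2 * DT
    assert mean_isi == pytest.approx(72.4042, abs=0.05)


def test_no_spikes_without_sodium():
    p = NeuronParams(g_na=0.0)
    assert len(run_single_neuron(p, duration=300.0)) == 0


def test_reference_isi_consistent_at_halved_dt():
    """Independent Euler oracle at dt/2: the dt = 2**-7 ms period is within
    the discretization error band of a dt-independent limit."""
    p = NeuronParams()
    dt2 = DT / 2
    v = -65.0
    m, n, h = (x_inf(x, v) for x in "mnh")
    spikes = []
    for it in range(int(1000.0 / dt2)):
        itot = ((p.g_na * ((m * m * m) * h)) * (p.e_na - v)
                + (p.g_k * ((n * n) * (n * n))) * (p.e_k - v)
                + p.g_l * (p.e_l - v))
        v2 = v + dt2 * itot / p.cm
        am, bm = rate_alpha("m", v), rate_beta("m", v)
        an, bn = rate_alpha("n", v), rate_beta("n", v)
        ah, bh = rate_alpha("h", v), rate_beta("h", v)
        m += dt2 * (am * (1 - m) - bm * m)
        n += dt2 * (an * (1 - n) - bn * n)
        h += dt2 * (ah * (1 - h) - bh * h)
        if v < -20.0 <= v2:
            spikes.append(it * dt2)
        v = v2
    _, isi_half = analysis.isi_stats(np.asarray(spikes), 1000.0)
    _, isi_full = analysis.isi_stats(run_single_neuron(p, 1000.0), 1000.0)
    assert isi_full == pytest.approx(isi_half, abs=0.15)


def test_reference_gating_stays_in_unit_interval():
    p = NeuronParams()
    v = -65.0
    m, n, h = (x_inf(x, v) for x in "mnh")
    ge = gi = 0.0
    for _ in range(int(200.0 / DT)):
        v, m, n, h, ge, gi = reference_step(p, v, m, n, h, ge, gi)
        assert 0.0 <= m <= 1.0 and 0.0 <= n <= 1.0 and 0.0 <= h <= 1.0


def test_fixed_and_reference_agree_on_spike_count(base_tables):
    ref = run_single_neuron(duration=2500.0)
    fix = run_single_neuron(duration=2500.0, mode="fixed", tables=base_tables)
    assert abs(len(ref) - len(fix)) <= 1
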