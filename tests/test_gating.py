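"""Gating curves and their piecewise-linear approximation."""

import numpy as np
import pytest

from hhfx import gating
from hhfx.fxp import Q9_24, quantize_raw
from hhfx.gating import (BASE_STEPS, DOUBLE_STEPS, HALF_STEPS,
                         GATING_FUNCTIONS, PwlTable, check_step_constraint,
                         eval_exact, export_hex_listing, export_table,
                         fit_boltzmann_gaussian, fit_pwl, import_table,
                         max_error, pwl_eval)

# tabulated max errors of the hardware design, in units of 1e-4
TABULATED_MAX_ERR = {
    "m_inf": {"Double": 23.49, "Base": 5.9610, "Half": 1.4936},
    "n_inf": {"Double": 18.881, "Base": 4.7894, "Half": 1.1999},
    "h_inf": {"Double": 20.2161, "Base": 5.1042, "Half": 1.2770},
    "inv_tau_m": {"Double": 11.8597, "Base": 2.9692, "Half": 0.80312},
    "inv_tau_n": {"Double": 17.8569, "Base": 4.5093, "Half": 1.1532},
    "inv_tau_h": {"Double": 12.8224, "Base": 3.2051, "Half": 0.80196},
}


def test_steady_states_are_probabilities_and_rates_positive():
    v = np.linspace(-100, 28, 500)
    for x in "mnh":
        s = eval_exact(x, "steady_state", v)
        r = eval_exact(x, "inv_tau", v)
        assert np.all((s > 0) & (s < 1))
        assert np.all(r > 0)


def test_sigmoid_midpoint_and_monotonicity():
    v = np.linspace(-100, 28, 2000)
    minf = eval_exact("m", "steady_state", v)
    hinf = eval_exact("h", "steady_state", v)
    assert np.all(np.diff(minf) > 0)       # activation rises with v
    assert np.all(np.diff(hinf) < 0)       # inactivation falls with v
    # half-activation voltage exists inside the domain
    assert minf[0] < 0.5 < minf[-1]


def test_boltzmann_gaussian_fit_matches_shapes():
    gp = fit_boltzmann_gaussian("m")
    # Boltzmann midpoint: steady state = 0.5 at v_half
    assert gp.steady_state(gp.v_half) == pytest.approx(0.5)
    # Gaussian center: tau peaks at v_peak
    assert gp.tau(gp.v_peak) == pytest.approx(gp.tau0 + gp.tau_amp)
    v = np.linspace(-100, 28, 400)
    err = np.abs(gp.steady_state(v) - eval_exact("m", "steady_state", v))
    assert err.max() < 0.05                # descriptive fit, not exact


def test_fit_pwl_linear_target_is_exact():
    t = fit_pwl(lambda v: 2.0 * v + 1.0, -16.0, 16.0, 4.0, "lin")
    assert np.allclose(t.a, 2.0) and np.allclose(t.b, 1.0)
    assert max_error(t, lambda v: 2.0 * v + 1.0, 0.01) < 1e-12


def test_fit_pwl_matches_normal_equation_oracle():
    f = GATING_FUNCTIONS["m_inf"]
    t = fit_pwl(f, -40.0, -24.0, 2.0, grid_per_segment=64)
    for j in range(t.n_segments):
        v = -40.0 + j * 2.0 + 2.0 * (np.arange(64) + 0.5) / 64
        y = f(v)
        # explicit 2x2 normal equations
        A = np.array([[len(v), v.sum()], [v.sum(), (v * v).sum()]])
        rhs = np.array([y.sum(), (v * y).sum()])
        b_j, a_j = np.linalg.solve(A, rhs)
        assert a_j == pytest.approx(t.a[j], rel=1e-9)
        assert b_j == pytest.approx(t.b[j], rel=1e-9)


def test_fit_pwl_rejects_bad_steps():
    with pytest.raises(ValueError):
        fit_pwl(np.sin, 0.0, 12.0, 3.0)    # not a power of two
    with pytest.raises(ValueError):
        fit_pwl(np.sin, 0.0, 10.0, 4.0)    # width not divisible


def test_base_max_errors_match_tabulated_design_values(base_tables):
    """The six Base-step tables reproduce the hardware design's tabulated
    least-squares approximation errors."""
    for name, t in base_tables.items():
        err = max_error(t, GATING_FUNCTIONS[name], 0.005) * 1e4
        expected = TABULATED_MAX_ERR[name]["Base"]
        assert err == pytest.approx(expected, rel=0.05), name


def test_halving_step_reduces_error_doubling_raises_quadratically(
        base_tables, double_tables, half_tables):
    for name in GATING_FUNCTIONS:
        f = GATING_FUNCTIONS[name]
        e_base = max_error(base_tables[name], f, 0.01)
        e_double = max_error(double_tables[name], f, 0.01)
        e_half = max_error(half_tables[name], f, 0.01)
        assert e_half < e_base < e_double
        # smooth targets: error scales roughly with step**2
        assert 2.5 < e_double / e_base < 6.5


def test_max_error_equals_finer_grid_bruteforce(base_tables):
    t = base_tables["m_inf"]
    f = GATING_FUNCTIONS["m_inf"]
    coarse = max_error(t, f, 0.01)
    fine = max_error(t, f, 0.001)
    assert fine == pytest.approx(coarse, rel=0.02)


def test_pwl_eval_segment_addressing(base_tables):
    t = base_tables["m_inf"]
    # at a segment's lower endpoint the j-th line is used
    j = 17
    v = t.v_lo + j * t.step
    assert pwl_eval(t, v) == pytest.approx(t.a[j] * v + t.b[j])
    # six-segment demo with a 16 mV step: address is the offset's top 3 bits
    demo = fit_pwl(GATING_FUNCTIONS["m_inf"], -64.0, 32.0, 16.0)
    assert demo.n_segments == 6
    for v, expect_j in [(-64.0, 0), (-33.0, 1), (0.0, 4), (31.9, 5)]:
        offset_bits = int((v - demo.v_lo) // 1) >> 4   # top 3 of 7-bit offset
        assert demo.segment_index(v) == expect_j == offset_bits


def test_pwl_eval_bounded_by_max_error_and_clamps(base_tables):
    t = base_tables["n_inf"]
    f = GATING_FUNCTIONS["n_inf"]
    bound = max_error(t, f, 0.001) + 1e-12
    v = np.arange(t.v_lo, t.v_hi, 0.003)
    assert np.all(np.abs(pwl_eval(t, v) - f(v)) <= bound)
    # out-of-domain clamps to the boundary segment's line
    assert pwl_eval(t, t.v_lo - 5.0) == pytest.approx(
        t.a[0] * (t.v_lo - 5.0) + t.b[0])
    assert pwl_eval(t, t.v_hi + 5.0) == pytest.approx(
        t.a[-1] * (t.v_hi + 5.0) + t.b[-1])


def test_fixed_mode_eval_matches_float_within_quantization(base_tables):
    t = base_tables["h_inf"]
    v = -55.3
    raw_v = quantize_raw(v, 24)
    out = pwl_eval(t, raw_v, mode="fixed") * 2.0 ** -24
    assert out == pytest.approx(pwl_eval(t, v), abs=1e-5)


def test_super_segment_merging_is_numerically_invisible():
    """Adjacent segments with identical (a, b) can be stored once; an
    evaluator over the merged table gives identical results."""
    f = lambda v: 0.5 * v - 3.0           # every segment identical
    t = fit_pwl(f, 0.0, 32.0, 4.0)
    merged_a, merged_b = t.a[:1], t.b[:1]   # one super segment
    for v in np.linspace(0.0, 31.9, 50):
        assert pwl_eval(t, v) == pytest.approx(merged_a[0] * v + merged_b[0])


@pytest.mark.parametrize("steps,ok", [
    (BASE_STEPS, True),
    (DOUBLE_STEPS, True),
    (HALF_STEPS, True),
    ({k: 2.0 for k in BASE_STEPS}, False),          # all-equal violates it
    ({k: 3.0 * v for k, v in BASE_STEPS.items()}, False),  # not powers of 2
])
def test_step_constraint(steps, ok):
    assert check_step_constraint(steps) is ok


def test_refit_is_bit_reproducible():
    f = GATING_FUNCTIONS["inv_tau_h"]
    t1 = fit_pwl(f, -100.0, 28.0, 0.5)
    t2 = fit_pwl(f, -100.0, 28.0, 0.5)
    assert np.array_equal(t1.a, t2.a) and np.array_equal(t1.b, t2.b)


def test_table_roundtrip_and_hex_listing(tmp_path, base_tables):
    t = base_tables["inv_tau_m"]
    p = tmp_path / "t.tsv"
    export_table(t, p)
    t2 = import_table(p)
    assert np.array_equal(t.a, t2.a) and np.array_equal(t.b, t2.b)
    assert (t2.v_lo, t2.v_hi, t2.step) == (t.v_lo, t.v_hi, t.step)
    hexp = tmp_path / "t.hex"
    export_hex_listing(t, hexp)
    lines = hexp.read_text().splitlines()
    assert len(lines) == t.n_segments
    # first pair decodes back to the quantized coefficients
    a_hex, b_hex = lines[0].split()
    raw_a = int(a_hex, 16)
    raw_a -= 1 << 33 if raw_a >= 1 << 32 else 0
    assert raw_a == int(t.raw_a[0])
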