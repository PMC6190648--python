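"""Gating-variable kinetics and their piecewise-linear approximation.

The neuron model is the conductance-based Hodgkin-Huxley benchmark network
cell (Traub-Miles kinetics shifted by a threshold parameter VT).  Each
gating variable x in {m, n, h} relaxes toward a voltage-dependent steady
state with a voltage-dependent time constant:

    dx/dt = (x_inf(v) - x) / tau_x(v),
    x_inf = alpha_x / (alpha_x + beta_x),   1/tau_x = alpha_x + beta_x.

`rate_alpha`/`rate_beta` give the rational closed forms; `eval_exact`
evaluates x_inf or the *inverse* time constant (the hardware approximates
1/tau, not tau, so no divider is needed).

For the fixed-point datapath the six functions are replaced by per-segment
straight lines y = a*v + b over equal power-of-two-wide intervals
("δ = 2**k mV"); per segment, (a, b) minimize the least-squares error on a
dense grid.  Segment lookup extracts high-order bits of the voltage word, so
the domain must start on a multiple of the step.  The default domain
[-100, 28) mV is 2**7 mV wide and covers the trajectory of the model with
margin; outside it, evaluation clamps to the boundary segment.

A Boltzmann/Gaussian parameterization (`GatingParams`) is provided as a
compact descriptive form of the same curves; the simulators target the
rational forms, whose PWL fits reproduce the tabulated approximation errors
of the hardware design (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Mapping

import numpy as np

from .fxp import FxFormat, Q9_24, quantize_raw, mul_raw

__all__ = [
    "VT", "rate_alpha", "rate_beta", "x_inf", "inv_tau", "eval_exact",
    "GATING_FUNCTIONS", "BASE_STEPS", "DOUBLE_STEPS", "HALF_STEPS",
    "GatingParams", "fit_boltzmann_gaussian",
    "PwlTable", "fit_pwl", "pwl_eval", "max_error", "check_step_constraint",
    "build_tables", "export_table", "import_table", "export_hex_listing",
]

#: spike-threshold shift of the Traub-Miles kinetics (mV)
VT = -63.0

#: default fitted domain, 2**7 mV wide (see module docstring)
V_LO_DEFAULT = -100.0
V_HI_DEFAULT = 28.0


def _ratexp(x, k):
    """x / expm1(x/k), with the removable singularity at x = 0 filled by k."""
    if isinstance(x, np.ndarray):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = x / np.expm1(x / k)
        return np.where(np.abs(x) < 1e-9, k, r)
    if abs(x) < 1e-9:
        return float(k)
    return x / np.expm1(x / k)


def rate_alpha(x: str, v):
    """Opening rate alpha_x(v) in 1/ms; v in mV."""
    if x == "m":
        return 0.32 * _ratexp(13.0 - v + VT, 4.0)
    if x == "n":
        return 0.032 * _ratexp(15.0 - v + VT, 5.0)
    if x == "h":
        return 0.128 * np.exp((17.0 - v + VT) / 18.0)
    raise ValueError(f"unknown gating variable {x!r}")


def rate_beta(x: str, v):
    """Closing rate beta_x(v) in 1/ms; v in mV."""
    if x == "m":
        return 0.28 * _ratexp(v - VT - 40.0, 5.0)
    if x == "n":
        return 0.5 * np.exp((10.0 - v + VT) / 40.0)
    if x == "h":
        return 4.0 / (1.0 + np.exp((40.0 - v + VT) / 5.0))
    raise ValueError(f"unknown gating variable {x!r}")


def x_inf(x: str, v):
    """Steady-state activation x_inf(v) = alpha/(alpha+beta), in (0, 1)."""
    a, b = rate_alpha(x, v), rate_beta(x, v)
    return a / (a + b)


def inv_tau(x: str, v):
    """Inverse time constant 1/tau_x(v) = alpha + beta, in 1/ms."""
    return rate_alpha(x, v) + rate_beta(x, v)


def eval_exact(x: str, kind: str, v):
    """Closed-form gating curve: kind is 'steady_state' or 'inv_tau'."""
    if kind == "steady_state":
        return x_inf(x, v)
    if kind == "inv_tau":
        return inv_tau(x, v)
    raise ValueError(f"unknown kind {kind!r}")


#: the six PWL targets, keyed by table id
GATING_FUNCTIONS: Dict[str, Callable] = {
    "m_inf": lambda v: x_inf("m", v),
    "n_inf": lambda v: x_inf("n", v),
    "h_inf": lambda v: x_inf("h", v),
    "inv_tau_m": lambda v: inv_tau("m", v),
    "inv_tau_n": lambda v: inv_tau("n", v),
    "inv_tau_h": lambda v: inv_tau("h", v),
}

# Step sizes (mV).  The error-balancing constraint of the design is
# dm = dn = d(1/tau_n) = 2*dh = 4*d(1/tau_h) = 4*d(1/tau_m).
BASE_STEPS = {"m_inf": 2.0, "n_inf": 2.0, "h_inf": 1.0,
              "inv_tau_m": 0.5, "inv_tau_n": 2.0, "inv_tau_h": 0.5}
DOUBLE_STEPS = {k: 2 * v for k, v in BASE_STEPS.items()}
HALF_STEPS = {k: v / 2 for k, v in BASE_STEPS.items()}


def check_step_constraint(steps: Mapping[str, float]) -> bool:
    """True iff the six step sizes balance per-table errors:
    dm = dn = d(1/tau_n) = 2*dh = 4*d(1/tau_h) = 4*d(1/tau_m),
    with every step a power of two."""
    try:
        vals = [steps[k] for k in ("m_inf", "n_inf", "h_inf",
                                   "inv_tau_m", "inv_tau_n", "inv_tau_h")]
    except KeyError:
        return False
    for s in vals:
        if s <= 0 or 2 ** round(math.log2(s)) != s:
            return False
    dm, dn, dh, dtm, dtn, dth = vals
    return dm == dn == dtn == 2 * dh == 4 * dth == 4 * dtm


@dataclass(frozen=True)
class GatingParams:
    """Boltzmann/Gaussian description of one gating variable's curves.

    x_inf is a Boltzmann sigmoid 1/(1 + exp((v_half - v)/slope)) (negative
    slope for inactivation); tau_x is a Gaussian bump
    tau0 + tau_amp * exp(-((v - v_peak)/width)**2) whose reciprocal is the
    inverse-time-constant curve.
    """

    name: str
    v_half: float
    slope: float
    tau0: float
    tau_amp: float
    v_peak: float
    width: float

    def steady_state(self, v):
        return 1.0 / (1.0 + np.exp((self.v_half - v) / self.slope))

    def tau(self, v):
        return self.tau0 + self.tau_amp * np.exp(-((v - self.v_peak) / self.width) ** 2)

    def inv_tau(self, v):
        return 1.0 / self.tau(v)


def fit_boltzmann_gaussian(x: str, v_lo: float = V_LO_DEFAULT,
                           v_hi: float = V_HI_DEFAULT,
                           n_grid: int = 2048) -> GatingParams:
    """Least-squares Boltzmann/Gaussian fit to the rational curves of x.

    These compact fits describe the curve shapes well but their residuals
    (1e-3..1e-1) are far larger than the PWL segment errors, and the tonic
    firing period is sensitive to them; they are therefore descriptive, not
    part of the simulation path.
    """
    from scipy.optimize import curve_fit

    v = np.linspace(v_lo, v_hi, n_grid)
    y_inf = x_inf(x, v)
    sgn = 1.0 if y_inf[-1] > y_inf[0] else -1.0

    def boltz(vv, vh, k):
        return 1.0 / (1.0 + np.exp((vh - vv) / k))

    (vh, k), _ = curve_fit(boltz, v, y_inf, p0=[-45.0, sgn * 6.0], maxfev=20000)

    y_tau = 1.0 / inv_tau(x, v)

    def gauss(vv, c0, c1, vp, w):
        return c0 + c1 * np.exp(-((vv - vp) / w) ** 2)

    p0 = [float(y_tau.min()), float(y_tau.max() - y_tau.min()),
          float(v[np.argmax(y_tau)]), 20.0]
    (c0, c1, vp, w), _ = curve_fit(gauss, v, y_tau, p0=p0, maxfev=20000)
    return GatingParams(x, float(vh), float(k), float(c0), float(c1),
                        float(vp), float(w))


# ---------------------------------------------------------------------------
# piecewise-linear tables
# ---------------------------------------------------------------------------

def _is_pow2(step: float) -> bool:
    return step > 0 and 2.0 ** round(math.log2(step)) == step


@dataclass(frozen=True)
class PwlTable:
    """Per-segment slope/intercept table over equal power-of-two intervals.

    Segment j covers [v_lo + j*step, v_lo + (j+1)*step) and evaluates
    a[j]*v + b[j].  ``raw_a``/``raw_b`` are the coefficients quantized into
    ``fmt`` (by truncation after fitting); float evaluation uses the
    unquantized ``a``/``b``.
    """

    name: str
    v_lo: float
    v_hi: float
    step: float
    a: np.ndarray
    b: np.ndarray
    fmt: FxFormat = Q9_24

    def __post_init__(self):
        if not _is_pow2(self.step):
            raise ValueError("step must be a power of two")
        n = (self.v_hi - self.v_lo) / self.step
        if abs(n - round(n)) > 1e-9 or round(n) != len(self.a):
            raise ValueError("domain width must be an integer number of steps")
        if self.v_lo / self.step != round(self.v_lo / self.step):
            raise ValueError("v_lo must be a multiple of step (bit addressing)")

    @property
    def n_segments(self) -> int:
        return len(self.a)

    @property
    def raw_a(self) -> np.ndarray:
        return quantize_raw(self.a, self.fmt.frac_bits)

    @property
    def raw_b(self) -> np.ndarray:
        return quantize_raw(self.b, self.fmt.frac_bits)

    def segment_index(self, v) -> np.ndarray:
        """floor((v - v_lo)/step), clamped to the table; for fixed-point
        words this is a pure bit-slice of the raw voltage."""
        j = np.floor((np.asarray(v, float) - self.v_lo) / self.step).astype(np.int64)
        return np.clip(j, 0, self.n_segments - 1)

    def segment_index_raw(self, v_raw, frac_bits: int | None = None):
        """Segment index from a raw fixed-point voltage by shifting: the
        hardware's 'high-order address bits' selection."""
        frac = self.fmt.frac_bits if frac_bits is None else frac_bits
        k = round(math.log2(self.step))
        lo_raw = quantize_raw(self.v_lo, frac)
        j = (v_raw - lo_raw) >> (frac + k)
        if isinstance(j, np.ndarray):
            return np.clip(j, 0, self.n_segments - 1)
        return min(max(int(j), 0), self.n_segments - 1)


def fit_pwl(func: Callable, v_lo: float, v_hi: float, step: float,
            name: str = "", grid_per_segment: int = 256,
            fmt: FxFormat = Q9_24) -> PwlTable:
    """Least-squares straight line per segment, on a dense in-segment grid.

    Midpoint-sampled grids make the normal equations well-conditioned and the
    result reproducible; coefficients are kept in double precision and only
    quantized on fixed-point evaluation.
    """
    if not _is_pow2(step):
        raise ValueError("step must be a power of two (2**k, k integer)")
    n_seg = (v_hi - v_lo) / step
    if abs(n_seg - round(n_seg)) > 1e-9:
        raise ValueError("domain width must be divisible by step")
    n_seg = int(round(n_seg))
    a = np.empty(n_seg)
    b = np.empty(n_seg)
    offs = step * (np.arange(grid_per_segment) + 0.5) / grid_per_segment
    for j in range(n_seg):
        v = v_lo + j * step + offs
        y = func(v)
        vm = v.mean()
        ym = y.mean()
        dv = v - vm
        a[j] = np.dot(dv, y - ym) / np.dot(dv, dv)
        b[j] = ym - a[j] * vm
    return PwlTable(name, v_lo, v_hi, step, a, b, fmt)


def pwl_eval(table: PwlTable, v, mode: str = "float"):
    """Evaluate the table at voltage(s) v.

    float mode: a[j]*v + b[j] in double precision, v in mV.
    fixed mode: v is a *raw* fixed-point voltage; the result is a raw word
    computed as mul(a_raw, v_raw) + b_raw with truncating semantics.
    Out-of-domain v clamps to the first/last segment.
    """
    if mode == "float":
        j = table.segment_index(v)
        out = table.a[j] * np.asarray(v, float) + table.b[j]
        return float(out) if np.ndim(v) == 0 else out
    if mode == "fixed":
        j = table.segment_index_raw(v)
        ra, rb = table.raw_a, table.raw_b
        if isinstance(v, np.ndarray):
            return mul_raw(ra[j], v, table.fmt.frac_bits) + rb[j]
        return mul_raw(int(ra[j]), int(v), table.fmt.frac_bits) + int(rb[j])
    raise ValueError(f"unknown mode {mode!r}")


def max_error(table: PwlTable, func: Callable, grid_step: float = 0.001) -> float:
    """Max |pwl - exact| over a dense grid spanning the table's domain."""
    v = np.arange(table.v_lo, table.v_hi, grid_step)
    return float(np.max(np.abs(pwl_eval(table, v) - func(v))))


def build_tables(steps: Mapping[str, float] | None = None,
                 v_lo: float = V_LO_DEFAULT, v_hi: float = V_HI_DEFAULT,
                 grid_per_segment: int = 256,
                 fmt: FxFormat = Q9_24) -> Dict[str, PwlTable]:
    """Fit all six gating tables (default: Base step sizes)."""
    steps = dict(BASE_STEPS if steps is None else steps)
    return {name: fit_pwl(GATING_FUNCTIONS[name], v_lo, v_hi, steps[name],
                          name=name, grid_per_segment=grid_per_segment, fmt=fmt)
            for name in GATING_FUNCTIONS}


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def export_table(table: PwlTable, path) -> None:
    """Delimited text: header + one `index  v_lo  a  b` row per segment."""
    with open(path, "w") as fh:
        fh.write(f"# pwl_table name={table.name} v_lo={table.v_lo!r} "
                 f"v_hi={table.v_hi!r} step={table.step!r} fmt={table.fmt}\n")
        fh.write("# segment\tv_lo\ta\tb\n")
        for j in range(table.n_segments):
            fh.write(f"{j}\t{table.v_lo + j * table.step!r}"
                     f"\t{float(table.a[j])!r}\t{float(table.b[j])!r}\n")


def import_table(path) -> PwlTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# pwl_table"):
            raise ValueError("not a PWL table file")
        meta = dict(kv.split("=", 1) for kv in header.split()[2:])
        rows = [ln.split("\t") for ln in fh if ln.strip() and not ln.startswith("#")]
    a = np.array([float(r[2]) for r in rows])
    b = np.array([float(r[3]) for r in rows])
    return PwlTable(meta["name"], float(meta["v_lo"]), float(meta["v_hi"]),
                    float(meta["step"]), a, b, FxFormat.from_string(meta["fmt"]))


def export_hex_listing(table: PwlTable, path) -> None:
    """Plain-text memory-initialization listing: one `AAAA BBBB` hex pair per
    segment, coefficients as unsigned two's-complement words of the table's
    format (hardware LUT interoperability)."""
    bits = table.fmt.total_bits
    width = (bits + 3) // 4
    mask = (1 << bits) - 1
    ra, rb = table.raw_a, table.raw_b
    with open(path, "w") as fh:
        for j in range(table.n_segments):
            fh.write(f"{int(ra[j]) & mask:0{width}x} "
                     f"{int(rb[j]) & mask:0{width}x}\n")
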