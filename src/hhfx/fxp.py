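"""Two's-complement Q-format fixed-point arithmetic, emulated bit-exactly.

Numbers are stored as signed raw integers; a word of format ``Qm.n`` (the
hardware convention: *m* integer bits including sign, *n* fractional bits)
represents ``raw * 2**-n`` in an ``m + n``-bit two's-complement word.  The
membrane voltage and synaptic conductances of the neuron pipeline live in
Q9.24 (33-bit words, unit in the last place 2**-24, range [-256, 256)); the
gating variables use the narrower Q2.24 storage format.

All operations reproduce the cheapest hardware realization: truncation
toward minus infinity (arithmetic shift) and two's-complement wraparound on
overflow, with a sticky flag so a simulation can report that it left the
designed dynamic range.  Round-to-nearest quantization is available for
sensitivity studies.

Scalar operations work on :class:`FxWord`; the raw-integer helpers
(`quantize_raw`, `mul_raw`, `wrap_raw`) operate on plain ints or numpy
``int64`` arrays and are what the vectorized network kernels use.  Raw int64
products are exact as long as ``|a*b| < 2**63``; callers keep operand
magnitudes well inside that (see `mul_raw`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "FxFormat", "FxWord", "OverflowFlags", "Q9_24", "Q2_24",
    "quantize", "fx_add", "fx_sub", "fx_mul", "fx_shift_right",
    "quantize_raw", "wrap_raw", "mul_raw", "shift_right_raw", "to_float",
]


@dataclass(frozen=True)
class FxFormat:
    """A Qm.n fixed-point format: ``int_bits`` integer bits (sign included),
    ``frac_bits`` fractional bits."""

    int_bits: int
    frac_bits: int

    def __post_init__(self) -> None:
        if self.int_bits < 1:
            raise ValueError("int_bits must be >= 1 (sign bit)")
        if self.frac_bits < 0:
            raise ValueError("frac_bits must be >= 0")

    @property
    def total_bits(self) -> int:
        return self.int_bits + self.frac_bits

    @property
    def ulp(self) -> float:
        """Gap between consecutive representable values, 2**-frac_bits."""
        return 2.0 ** -self.frac_bits

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def min_value(self) -> float:
        return self.raw_min * self.ulp

    @property
    def max_value(self) -> float:
        return self.raw_max * self.ulp

    @classmethod
    def from_string(cls, s: str) -> "FxFormat":
        """Parse a ``"Qm.n"`` format string, e.g. ``"Q9.24"``."""
        if not s.startswith(("Q", "q")) or "." not in s:
            raise ValueError(f"not a Qm.n format string: {s!r}")
        m, n = s[1:].split(".", 1)
        return cls(int(m), int(n))

    def __str__(self) -> str:
        return f"Q{self.int_bits}.{self.frac_bits}"


#: word format of v, g_e, g_i and of all datapath arithmetic
Q9_24 = FxFormat(9, 24)
#: reduced storage format of the gating variables m, n, h
Q2_24 = FxFormat(2, 24)


@dataclass
class OverflowFlags:
    """Sticky overflow indicator shared across a computation.

    The hardware sized its integer bits so that overflow never occurs in a
    well-behaved run; any set flag is therefore a diagnostic, not a normal
    outcome."""

    count: int = 0

    def __bool__(self) -> bool:
        return self.count > 0

    def note(self, n: int = 1) -> None:
        self.count += n


@dataclass(frozen=True)
class FxWord:
    """An immutable fixed-point word: raw two's-complement integer + format."""

    raw: int
    fmt: FxFormat

    @property
    def value(self) -> float:
        return self.raw * self.fmt.ulp

    def __float__(self) -> float:
        return self.value

    @classmethod
    def from_float(cls, x: float, fmt: FxFormat = Q9_24,
                   mode: str = "truncate",
                   flags: OverflowFlags | None = None) -> "FxWord":
        return quantize(x, fmt, mode, flags)


def wrap_raw(raw: Union[int, np.ndarray], fmt: FxFormat,
             flags: OverflowFlags | None = None):
    """Reduce a raw integer into the two's-complement range of ``fmt``.

    Values already in range pass through unchanged; out-of-range values wrap
    exactly as an ``fmt.total_bits``-wide hardware register would, and the
    sticky ``flags`` object (if given) is notified.
    """
    span = 1 << fmt.total_bits
    half = 1 << (fmt.total_bits - 1)
    if isinstance(raw, np.ndarray):
        out = (raw + half) % span - half
        if flags is not None:
            bad = int(np.count_nonzero(out != raw))
            if bad:
                flags.note(bad)
        return out
    wrapped = (int(raw) + half) % span - half
    if flags is not None and wrapped != raw:
        flags.note()
    return wrapped


def quantize_raw(x, frac_bits: int, mode: str = "truncate"):
    """Real value -> unbounded raw integer at 2**-frac_bits resolution."""
    scaled = np.multiply(x, float(1 << frac_bits), dtype=np.float64)
    if mode == "truncate":
        raw = np.floor(scaled)
    elif mode == "round_nearest":
        raw = np.floor(scaled + 0.5)
    else:
        raise ValueError(f"unknown rounding mode: {mode!r}")
    if np.ndim(x) == 0:
        return int(raw)
    return raw.astype(np.int64)


def quantize(x: float, fmt: FxFormat = Q9_24, mode: str = "truncate",
             flags: OverflowFlags | None = None) -> FxWord:
    """Quantize a real number into ``fmt``.

    Truncation rounds toward minus infinity (result <= x); round_nearest ties
    away from the floor.  An out-of-range x wraps two's-complement style and
    sets the overflow flag -- the returned word carries the wrapped value.
    """
    raw = quantize_raw(float(x), fmt.frac_bits, mode)
    return FxWord(wrap_raw(raw, fmt, flags), fmt)


def _check_fmt(a: FxWord, b: FxWord) -> None:
    if a.fmt != b.fmt:
        raise ValueError(f"format mismatch: {a.fmt} vs {b.fmt}")


def fx_add(a: FxWord, b: FxWord, flags: OverflowFlags | None = None) -> FxWord:
    _check_fmt(a, b)
    return FxWord(wrap_raw(a.raw + b.raw, a.fmt, flags), a.fmt)


def fx_sub(a: FxWord, b: FxWord, flags: OverflowFlags | None = None) -> FxWord:
    _check_fmt(a, b)
    return FxWord(wrap_raw(a.raw - b.raw, a.fmt, flags), a.fmt)


def mul_raw(a, b, frac_bits: int = 24):
    """Raw fixed-point multiply: full product arithmetic-shifted right.

    ``(a * b) >> frac_bits`` with floor semantics, i.e. truncation toward
    minus infinity -- exactly what a two's-complement multiplier followed by
    a wire shift produces.  For numpy int64 operands the caller must keep
    ``|a*b| < 2**63``; with Q9.24 operands that holds whenever the product of
    the represented values stays below 2**15 = 32768, far above the designed
    |value| < 256 dynamic range.
    """
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return (a * b) >> frac_bits
    return (int(a) * int(b)) >> frac_bits


def fx_mul(a: FxWord, b: FxWord, out_fmt: FxFormat | None = None,
           flags: OverflowFlags | None = None) -> FxWord:
    """Fixed-point multiply; inputs must share frac_bits.

    The full-precision raw product is right-shifted by frac_bits (truncating
    toward -inf) and range-reduced into ``out_fmt`` (default: a's format).
    """
    if a.fmt.frac_bits != b.fmt.frac_bits:
        raise ValueError("operands must share frac_bits")
    out_fmt = out_fmt or a.fmt
    raw = (a.raw * b.raw) >> a.fmt.frac_bits
    return FxWord(wrap_raw(raw, out_fmt, flags), out_fmt)


def shift_right_raw(raw, k: int):
    """Arithmetic right shift by k (floor division by 2**k)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return raw >> k


def fx_shift_right(a: FxWord, k: int) -> FxWord:
    """Arithmetic right shift: the hardware's multiply-by-2**-k.

    Every multiplication by dt = 2**-7 ms in the neuron pipeline is this
    operation with k = 7.  Never overflows (magnitude shrinks).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return FxWord(a.raw >> k, a.fmt)


def to_float(raw, frac_bits: int = 24):
    """Raw integer (scalar or array) -> real value."""
    if isinstance(raw, np.ndarray):
        return raw.astype(np.float64) * 2.0 ** -frac_bits
    return float(raw) * 2.0 ** -frac_bits
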