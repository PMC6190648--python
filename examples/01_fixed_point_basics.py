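"""Q9.24 fixed-point arithmetic: quantization, truncation and wraparound.

The datapath stores every number as a 33-bit two's-complement integer with
24 fractional bits, so the gap between representable values is 2**-24 and
the range is [-256, 256).  Multiplies truncate toward minus infinity;
multiplying by the 2**-7 ms time step is just an arithmetic right shift.
"""

from hhfx import FxWord, OverflowFlags, Q9_24, fx_add, fx_mul, fx_shift_right, quantize

x = quantize(-65.4321, Q9_24)
print(f"quantize(-65.4321) -> raw {x.raw}, value {x.value:.7f}")
print(f"  (truncation toward -inf: value <= input, error < ulp = {Q9_24.ulp:.3e})")

a, b = quantize(0.5), quantize(0.25)
print(f"0.5 * 0.25 = {fx_mul(a, b).value}  (exact: both operands representable)")

tiny = FxWord(1, Q9_24)       # one ulp
print(f"ulp * ulp = {fx_mul(tiny, tiny).raw} raw  (truncates to zero)")

v = quantize(1.0)
print(f"1.0 >> 7 = {fx_shift_right(v, 7).value}  (the dt = 2**-7 ms multiply)")

flags = OverflowFlags()
mx = FxWord(Q9_24.raw_max, Q9_24)
wrapped = fx_add(mx, FxWord(1, Q9_24), flags)
print(f"max + ulp wraps to {wrapped.value} with overflow flag = {bool(flags)}")
print("  (the hardware sized its 9 integer bits so this never happens in a run)")
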