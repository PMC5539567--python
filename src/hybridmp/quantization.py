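"""Fixed-point (Q-format) emulation of the inference chain.

A Q(m, n) number has m integer and n fractional bits: values live on the
2^-n grid and saturate at +/-(2^m - 2^-n) (or wrap, if configured).  The
floating-point pipeline is re-run with every signal block, every set of
coefficients/weights, and every stage output snapped to its configured
format, emulating a fixed-point datapath at stage granularity (training
stays in floating point: data-dependent models are fitted in software and
the quantized chain only performs inference).  The point of the exercise is
parity: with realistic formats the binary decision streams of the quantized
and double-precision pipelines agree to well over 99%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["QFormat", "QuantizationScheme", "quantize", "default_formats"]


@dataclass(frozen=True)
class QFormat:
    int_bits: int = 8
    frac_bits: int = 24
    rounding: str = "nearest"   # or "truncate"
    overflow: str = "saturate"  # or "wrap"

    def __post_init__(self) -> None:
        if self.int_bits < 0 or self.frac_bits < 0:
            raise ValueError("bit counts must be >= 0")
        if self.int_bits + self.frac_bits > 64:
            raise ValueError("m + n must be <= 64")
        if self.rounding not in ("nearest", "truncate"):
            raise ValueError("rounding must be 'nearest' or 'truncate'")
        if self.overflow not in ("saturate", "wrap"):
            raise ValueError("overflow must be 'saturate' or 'wrap'")

    @property
    def resolution(self) -> float:
        return 2.0 ** (-self.frac_bits)

    @property
    def max_value(self) -> float:
        return 2.0**self.int_bits - self.resolution


def quantize(value, fmt: QFormat):
    """Snap value(s) to the Q(m, n) grid; idempotent and monotone.

    Nearest rounding is round-half-up (0.3 in Q(2,4): 0.3*16 = 4.8 -> 5 ->
    0.3125); truncation rounds toward zero.  Overflow saturates at
    +/-(2^m - 2^-n) or wraps around the two's-complement range.
    """
    x = np.asarray(value, dtype=np.float64)
    scale = 2.0**fmt.frac_bits
    if fmt.rounding == "nearest":
        q = np.floor(x * scale + 0.5)
    else:
        q = np.trunc(x * scale)
    if fmt.overflow == "saturate":
        hi = 2.0 ** (fmt.int_bits + fmt.frac_bits) - 1.0
        q = np.clip(q, -hi, hi)
    else:
        period = 2.0 ** (fmt.int_bits + fmt.frac_bits + 1)
        half = period / 2.0
        q = np.mod(q + half, period) - half
    out = q / scale
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(out)
    return out


@dataclass
class QuantizationScheme:
    """Per-role formats applied throughout the inference chain.

    ``signal`` covers raw/processed sample blocks and feature vectors,
    ``coeff`` the static FIR taps / spatial-filter / classifier weights, and
    ``accum`` wide intermediate results (running variances, thresholds,
    decision scores).  Tracks the fraction of saturated samples and warns
    when it exceeds 1%.
    """

    signal: QFormat = QFormat(8, 24)
    coeff: QFormat = QFormat(8, 24)
    accum: QFormat = QFormat(16, 32)
    _n_seen: int = field(default=0, repr=False)
    _n_sat: int = field(default=0, repr=False)

    def _apply(self, x, fmt: QFormat):
        arr = np.asarray(x, dtype=np.float64)
        if fmt.overflow == "saturate":
            self._n_seen += arr.size
            self._n_sat += int(np.count_nonzero(np.abs(arr) > fmt.max_value))
        return quantize(x, fmt)

    def q_signal(self, x):
        return self._apply(x, self.signal)

    def q_coeff(self, x):
        return self._apply(x, self.coeff)

    def q_accum(self, x):
        return self._apply(x, self.accum)

    @property
    def saturation_fraction(self) -> float:
        return self._n_sat / self._n_seen if self._n_seen else 0.0

    def warn_if_saturating(self) -> None:
        import warnings

        if self.saturation_fraction > 0.01:
            warnings.warn(
                f"{100 * self.saturation_fraction:.1f}% of samples saturate; "
                "formats are probably too narrow",
                stacklevel=2,
            )


def default_formats() -> QuantizationScheme:
    """Fresh scheme with the default formats (separate saturation counters)."""
    return QuantizationScheme()
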