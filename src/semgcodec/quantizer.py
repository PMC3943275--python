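"""Per-sub-band quantization of the transform coefficients and its inverse.

Quantization law (per coefficient, with m the coefficient's sub-band):

    X_q[k] = int( X[k] / 2**(R-1) * lambda_m ),    lambda_m = 2**B[m]

``int`` truncates toward zero, so the quantizer is odd-symmetric and
introduces no DC bias; the decoder mirrors the same convention.  Symbols are
clamped to [-lambda_m, +lambda_m] (alphabet size 2*lambda_m + 1): the
orthonormal transform bounds the coefficient energy, not the maximum, so the
occasional coefficient beyond the nominal dynamic range is clamped rather
than assumed away.  Sub-bands allocated zero bits discard their
coefficients entirely (all symbols forced to 0).

Inverse:  X_hat[k] = X_q[k] * 2**(R-1) / lambda_m, so the per-coefficient
error of an unclamped coefficient is below one step 2**(R-1)/lambda_m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .allocation import AllocationPlan
from .errors import ParameterError
from .transform import CoefficientWindow

__all__ = ["QuantizedWindow", "quantize", "dequantize"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantizedWindow:
    """Integer symbol vector X_q[k] with its allocation plan and word length."""

    symbols: np.ndarray
    plan: AllocationPlan
    bit_depth: int
    clamped: int = 0  # coefficients that hit the +/-lambda_m clamp

    @property
    def length(self) -> int:
        return int(self.symbols.size)


def _per_coefficient_lambdas(plan: AllocationPlan, n: int) -> np.ndarray:
    m = plan.sub_band_count
    if n % m:
        raise ParameterError(f"M={m} does not divide N={n}")
    return np.repeat(plan.scale_factors, n // m)


def quantize(coeffs: CoefficientWindow, plan: AllocationPlan,
             bit_depth: int = 16) -> QuantizedWindow:
    """Apply the truncating quantization law sub-band by sub-band."""
    x = np.asarray(coeffs.coefficients, dtype=np.float64)
    lam = _per_coefficient_lambdas(plan, x.size)
    half_scale = float(1 << (bit_depth - 1))
    raw = np.trunc(x / half_scale * lam)
    clipped = np.clip(raw, -lam, lam)
    n_clamped = int(np.count_nonzero(raw != clipped))
    if n_clamped:
        log.warning("%d coefficients clamped to +/-lambda_m", n_clamped)
    symbols = clipped.astype(np.int64)
    symbols[np.repeat(plan.bits, x.size // plan.sub_band_count) == 0] = 0
    return QuantizedWindow(symbols, plan, bit_depth, n_clamped)


def dequantize(qwin: QuantizedWindow, levels: int, wavelet_name: str) -> CoefficientWindow:
    """Invert the quantization law: X_hat[k] = X_q[k] * 2**(R-1) / lambda_m."""
    lam = _per_coefficient_lambdas(qwin.plan, qwin.length)
    half_scale = float(1 << (qwin.bit_depth - 1))
    xhat = qwin.symbols.astype(np.float64) * half_scale / lam
    return CoefficientWindow(xhat, levels, wavelet_name)
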