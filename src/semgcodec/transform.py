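"""Orthonormal discrete wavelet transform of one window and its inverse.

Each length-N window is decomposed with an orthogonal Daubechies wavelet
(default ``db4``, i.e. 4 vanishing moments / 8 taps) over 8 dyadic levels
using periodized boundary handling, so the map is exactly orthonormal:
the coefficient vector has length N and preserves energy (Parseval).
Coefficients are ordered coarse-to-fine,
``[approx_L, detail_L, detail_{L-1}, ..., detail_1]``, so the index grows
with frequency — the premise of the decreasing bit-allocation shapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import FormatError, ParameterError

__all__ = ["CoefficientWindow", "forward_dwt", "inverse_dwt", "round_to_integer"]

log = logging.getLogger(__name__)

DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 8

# Orthonormality requires the periodized transform; symmetric extension would
# inflate the coefficient count beyond N.
_MODE = "periodization"


@dataclass(frozen=True)
class CoefficientWindow:
    """Length-N transform-coefficient vector for one window, coarse to fine."""

    coefficients: np.ndarray
    levels: int
    wavelet_name: str

    @property
    def length(self) -> int:
        return int(self.coefficients.size)


def _check_geometry(n: int, wavelet_name: str, levels: int) -> pywt.Wavelet:
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ParameterError(f"unknown wavelet {wavelet_name!r}") from exc
    if not wavelet.orthogonal:
        raise ParameterError(f"wavelet {wavelet_name!r} is not orthogonal")
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    if n % (1 << levels):
        raise ParameterError(
            f"window length {n} is not divisible by 2**levels = {1 << levels}"
        )
    return wavelet


def forward_dwt(
    window: np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> CoefficientWindow:
    """Decompose one window into its length-N orthonormal DWT coefficients."""
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ParameterError("window must be a nonempty 1-D array")
    wavelet = _check_geometry(x.size, wavelet_name, levels)
    parts = pywt.wavedec(x, wavelet, mode=_MODE, level=levels)
    coeffs = np.concatenate(parts)
    if coeffs.size != x.size:
        raise FormatError(
            f"periodized DWT returned {coeffs.size} coefficients for N={x.size}"
        )
    return CoefficientWindow(coeffs, levels, wavelet_name)


def inverse_dwt(coeffs: CoefficientWindow) -> np.ndarray:
    """Reconstruct the real-valued window; exact inverse of forward_dwt."""
    n = coeffs.length
    wavelet = _check_geometry(n, coeffs.wavelet_name, coeffs.levels)
    # split flat vector back into [cA_L, cD_L, ..., cD_1]
    lengths = [n >> coeffs.levels]
    lengths += [n >> lev for lev in range(coeffs.levels, 0, -1)]
    if sum(lengths) != n:
        raise FormatError("coefficient length is not a valid dyadic structure")
    parts = []
    pos = 0
    for ln in lengths:
        parts.append(np.asarray(coeffs.coefficients[pos : pos + ln], dtype=np.float64))
        pos += ln
    return pywt.waverec(parts, wavelet, mode=_MODE)


def round_to_integer(window: np.ndarray, bit_depth: int = 16) -> np.ndarray:
    """Round half away from zero, then clamp to the bit-depth range."""
    x = np.asarray(window, dtype=np.float64)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    lo = -(1 << (bit_depth - 1))
    hi = (1 << (bit_depth - 1)) - 1
    return np.clip(rounded, lo, hi).astype(np.int64)


def dynamic_range_violations(coeffs: CoefficientWindow, bit_depth: int) -> int:
    """Count coefficients exceeding 2**(R-1) in magnitude.

    Orthonormality bounds the coefficient 2-norm, not the max, so the
    dynamic-range assumption can fail on pathological windows; the quantizer
    clamps, and callers may log this counter.
    """
    bound = float(1 << (bit_depth - 1))
    count = int(np.count_nonzero(np.abs(coeffs.coefficients) > bound))
    if count:
        log.warning("%d coefficients exceed the 2**(R-1) dynamic-range bound", count)
    return count
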