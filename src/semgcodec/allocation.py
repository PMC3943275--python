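"""Dynamic bit allocation from decreasing spectral-shape models.

The wavelet coefficient vector is split into ``M`` equal sub-bands; each
sub-band ``m`` is quantized with ``B[m]`` bits taken from a decreasing curve
between ``Q`` (bits for the lowest, highest-energy sub-band) and ``L`` (bits
for the highest sub-band).  Four shapes are provided:

==========  ==============================================================
``dla``     decreasing linear:        B[m] = ceil(Q - (Q-L)/(M-1) * m)
``dsr``     decreasing square-root:   B[m] = ceil(xi * sqrt(C - m))
``dea``     decreasing exponential:   B[m] = ceil(b ** (p - m))
``rht``     rotated hyperbolic tan:   B[m] = ceil(Q/2 * (1 - tanh(a(m - M b))))
==========  ==============================================================

For dla/dsr/dea the curve passes exactly through B[0]=Q and B[M-1]=L; the
rht curve is clamped into [L, Q].  ``ceil`` here is the "smallest integer
not below" rounding — the only rounding that preserves the stated Q/L
endpoints.  The sub-band scale factor is lambda_m = 2**B[m].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "AllocationPlan",
    "allocate",
    "allocate_dla",
    "allocate_dsr",
    "allocate_dea",
    "allocate_rht",
    "scale_factors",
    "subband_of",
    "SHAPES",
]

SHAPES = ("dla", "dsr", "dea", "rht")

# guard against float noise pushing an exact integer endpoint over the next
# integer: ceil(Q + 1 ulp) would otherwise yield Q + 1
_CEIL_EPS = 1e-9


def _intsup(x: float) -> int:
    return int(math.ceil(x - _CEIL_EPS))


@dataclass(frozen=True)
class AllocationPlan:
    """Per-sub-band word lengths B[m] and scale factors lambda_m = 2**B[m]."""

    shape: str
    sub_band_count: int
    max_bits: int
    min_bits: int
    bits: np.ndarray
    alpha: float = 0.0
    beta: float = 0.0
    scale_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int64)
        if bits.size != self.sub_band_count:
            raise ParameterError("bits vector length must equal sub_band_count")
        if bits.min() < 0:
            raise ParameterError("negative bit counts are not allowed")
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "scale_factors", (1 << bits.astype(np.int64)))


def _check_common(Q: int, L: int, M: int) -> None:
    if M < 2:
        raise ParameterError(f"need at least 2 sub-bands, got M={M}")
    if L < 0 or Q < L:
        raise ParameterError(f"need 0 <= L <= Q, got Q={Q}, L={L}")


def _flat(shape: str, Q: int, M: int, alpha: float = 0.0, beta: float = 0.0) -> AllocationPlan:
    return AllocationPlan(shape, M, Q, Q, np.full(M, Q, dtype=np.int64), alpha, beta)


def allocate_dla(Q: int, L: int, M: int) -> AllocationPlan:
    """Linearly decreasing word length from Q down to L."""
    _check_common(Q, L, M)
    slope = (Q - L) / (M - 1)
    bits = np.array([_intsup(Q - slope * m) for m in range(M)], dtype=np.int64)
    return AllocationPlan("dla", M, Q, L, bits)


def allocate_dsr(Q: int, L: int, M: int) -> AllocationPlan:
    """Square-root-decay word length; endpoints pinned to Q and L."""
    _check_common(Q, L, M)
    if L == Q:
        return _flat("dsr", Q, M)
    c = Q * Q * (1 - M) / (L * L - Q * Q)
    xi = Q / math.sqrt(c)
    bits = np.array([_intsup(xi * math.sqrt(c - m)) for m in range(M)], dtype=np.int64)
    return AllocationPlan("dsr", M, Q, L, bits)


def allocate_dea(Q: int, L: int, M: int) -> AllocationPlan:
    """Exponentially decaying word length; requires Q, L > 1 for the logs."""
    _check_common(Q, L, M)
    if L == Q:
        return _flat("dea", Q, M)
    if L <= 1 or Q <= 1:
        raise ParameterError("dea requires Q > L >= 2 (logarithms degenerate)")
    p = (1 - M) / (math.log10(L) / math.log10(Q) - 1)
    b = Q ** (1 / p)
    bits = np.array([_intsup(b ** (p - m)) for m in range(M)], dtype=np.int64)
    return AllocationPlan("dea", M, Q, L, bits)


def allocate_rht(Q: int, L: int, M: int, alpha: float = 0.4, beta: float = 0.5) -> AllocationPlan:
    """Reflected sigmoid (rotated tanh) word length, clamped into [L, Q].

    ``alpha`` sets the transition steepness, ``beta`` the midpoint as a
    fraction of M; at m = M*beta the unclamped curve passes ceil(Q/2).
    """
    _check_common(Q, L, M)
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    if not 0 <= beta <= 1:
        raise ParameterError("beta must be in [0, 1]")
    raw = [
        _intsup(Q / 2 * (1 - math.tanh(alpha * (m - M * beta))))
        for m in range(M)
    ]
    bits = np.clip(np.asarray(raw, dtype=np.int64), L, Q)
    return AllocationPlan("rht", M, Q, L, bits, alpha, beta)


def allocate(shape: str, Q: int, L: int, M: int,
             alpha: float = 0.4, beta: float = 0.5) -> AllocationPlan:
    """Dispatch on shape name (case-insensitive)."""
    shape = shape.lower()
    if shape == "dla":
        return allocate_dla(Q, L, M)
    if shape == "dsr":
        return allocate_dsr(Q, L, M)
    if shape == "dea":
        return allocate_dea(Q, L, M)
    if shape == "rht":
        return allocate_rht(Q, L, M, alpha, beta)
    raise ParameterError(f"unknown shape {shape!r}; expected one of {SHAPES}")


def scale_factors(plan: AllocationPlan) -> np.ndarray:
    """lambda_m = 2**B[m], exact integer powers."""
    return plan.scale_factors


def subband_of(k: int | np.ndarray, n: int, m_bands: int) -> int | np.ndarray:
    """Map coefficient index k to its sub-band index m = floor(k / (N/M))."""
    if n % m_bands:
        raise ParameterError(f"M={m_bands} does not divide N={n}")
    width = n // m_bands
    idx = np.asarray(k)
    if np.any(idx < 0) or np.any(idx >= n):
        raise ParameterError("coefficient index out of range")
    out = idx // width
    return int(out) if np.isscalar(k) else out
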