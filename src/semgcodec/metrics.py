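"""Rate-distortion evaluation: compression factor, PRD, and grid sweeps.

Compression factor (percent saving) and percent residual difference::

    CF  = (O_S - C_S) / O_S * 100
    PRD = sqrt( sum (x - x_hat)**2 / sum x**2 ) * 100

with O_S / C_S the original / compressed sizes in bits and the sums over
the full K-sample signal on raw ADC counts (no normalization or mean
removal).  ``rd_sweep`` traces CF-PRD curves by compressing a bank of
signals over a grid of (shape, Q, L) settings.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .container import CodecConfig, compress, decompress
from .errors import ParameterError, SemgCodecError
from .signal_io import SignalRecord

__all__ = [
    "RateDistortionPoint",
    "compression_factor",
    "percent_residual_difference",
    "rd_sweep",
    "bin_curve",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateDistortionPoint:
    """One (CF, PRD) measurement together with the codec settings used."""

    signal_id: str
    shape: str
    q_bits: int
    l_bits: int
    alpha: float
    beta: float
    cf: float
    prd: float
    original_bits: int
    compressed_bits: int


def compression_factor(original_bits: float, compressed_bits: float) -> float:
    """CF in percent of the original size saved."""
    if original_bits <= 0:
        raise ParameterError("original size must be positive")
    return (original_bits - compressed_bits) / original_bits * 100.0


def percent_residual_difference(x: SignalRecord | np.ndarray,
                                xhat: SignalRecord | np.ndarray) -> float:
    """PRD in percent; energy-normalized rms of the reconstruction error."""
    a = x.samples if isinstance(x, SignalRecord) else np.asarray(x)
    b = xhat.samples if isinstance(xhat, SignalRecord) else np.asarray(xhat)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("signals must be equal-length 1-D")
    if a.size == 0:
        raise ParameterError("PRD is undefined for empty signals")
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    energy = float(np.dot(a, a))
    if energy == 0.0:
        raise ParameterError("PRD is undefined for an all-zero reference")
    return float(np.sqrt(np.dot(a - b, a - b) / energy) * 100.0)


def evaluate_point(record: SignalRecord, config: CodecConfig,
                   signal_id: str = "signal") -> RateDistortionPoint:
    """Compress, decompress, and measure one rate-distortion point."""
    stream = compress(record, config)
    recon = decompress(stream)
    o_bits = record.length * record.bit_depth
    c_bits = stream.total_size_bytes * 8
    return RateDistortionPoint(
        signal_id=signal_id, shape=config.shape,
        q_bits=config.q_bits, l_bits=config.l_bits,
        alpha=config.alpha, beta=config.beta,
        cf=compression_factor(o_bits, c_bits),
        prd=percent_residual_difference(record, recon),
        original_bits=o_bits, compressed_bits=c_bits,
    )


def rd_sweep(signals: Sequence[SignalRecord] | dict[str, SignalRecord],
             shapes: Iterable[str] = ("dla", "dsr", "dea", "rht"),
             q_grid: Iterable[int] = range(15, 1, -1),
             l_grid: Iterable[int] = (2,),
             config: CodecConfig | None = None) -> pd.DataFrame:
    """Sweep the codec over a (signal, shape, Q, L) grid.

    Returns a tidy DataFrame with one row per grid point; combinations a
    shape cannot realize (e.g. Q < L, or L < 2 for the exponential shape)
    are skipped, and codec failures are logged and skipped rather than
    aborting the sweep.
    """
    base = config or CodecConfig()
    if not isinstance(signals, dict):
        signals = {f"signal{i:02d}": s for i, s in enumerate(signals)}
    rows = []
    for sig_id, record in signals.items():
        for shape in shapes:
            for l_bits in l_grid:
                for q_bits in q_grid:
                    if q_bits < l_bits:
                        continue
                    if shape == "dea" and (l_bits < 2 or q_bits < 2):
                        continue
                    cfg = replace(base, shape=shape, q_bits=q_bits, l_bits=l_bits)
                    try:
                        point = evaluate_point(record, cfg, sig_id)
                    except SemgCodecError as exc:
                        log.warning("skipping %s %s Q=%d L=%d: %s",
                                    sig_id, shape, q_bits, l_bits, exc)
                        continue
                    rows.append(asdict(point))
    return pd.DataFrame(rows)


def bin_curve(points: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    """Average PRD per shape within CF bins, for bank-level CF-PRD curves."""
    df = points.copy()
    df["cf_bin"] = np.floor(df["cf"] / bin_width) * bin_width
    out = (df.groupby(["shape", "cf_bin"], as_index=False)
             .agg(prd_mean=("prd", "mean"), n_points=("prd", "size")))
    return out.sort_values(["shape", "cf_bin"]).reset_index(drop=True)
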