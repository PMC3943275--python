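"""Waveform I/O and windowing.

Surface EMG recordings enter the codec as single-channel integer sample
streams, typically 16-bit words sampled at 2 kHz.  Three on-disk formats are
supported: 16-bit PCM WAV (mono), raw little-endian int16, and plain text
with one sample value per line.  The codec operates on fixed-length windows
of ``N`` samples; the final window is zero-padded and the original length is
kept so the decoder can truncate the padding away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile

from .errors import FormatError, ParameterError

__all__ = [
    "SignalRecord",
    "WindowSet",
    "read_signal",
    "write_signal",
    "segment",
    "reassemble",
]

DEFAULT_SAMPLE_RATE = 2000.0  # Hz; surface EMG convention for both protocols

FORMATS = ("wav16", "raw_int16", "text")


def _int_bounds(bit_depth: int) -> tuple[int, int]:
    return -(1 << (bit_depth - 1)), (1 << (bit_depth - 1)) - 1


@dataclass(frozen=True)
class SignalRecord:
    """A single-channel integer-sampled waveform.

    Parameters
    ----------
    samples : ndarray of integers
        ADC counts, shape ``(K,)``.
    sample_rate : float
        Sampling rate in Hz; metadata only, never used by the codec math.
    bit_depth : int
        Word length R in bits; samples must lie in ``[-2**(R-1), 2**(R-1)-1]``.
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    bit_depth: int = 16

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples)
        if arr.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if not np.issubdtype(arr.dtype, np.integer):
            if arr.size and not np.all(arr == np.round(arr)):
                raise ParameterError("samples must be integer-valued")
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if not 8 <= self.bit_depth <= 32:
            raise ParameterError(f"bit_depth must be in 8..32, got {self.bit_depth}")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        lo, hi = _int_bounds(self.bit_depth)
        if arr.size and (arr.min() < lo or arr.max() > hi):
            raise ParameterError(
                f"samples exceed the {self.bit_depth}-bit range [{lo}, {hi}]"
            )
        object.__setattr__(self, "samples", arr)

    @property
    def length(self) -> int:
        """Total length K in samples."""
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.length / self.sample_rate


@dataclass(frozen=True)
class WindowSet:
    """The signal cut into consecutive length-N blocks, last block zero-padded."""

    windows: np.ndarray  # shape (n_windows, N), int64
    original_length: int
    pad_count: int
    sample_rate: float = DEFAULT_SAMPLE_RATE
    bit_depth: int = 16

    @property
    def window_length(self) -> int:
        return int(self.windows.shape[1]) if self.windows.size else 0

    @property
    def n_windows(self) -> int:
        return int(self.windows.shape[0])


def read_signal(
    path: str | Path,
    fmt: str = "wav16",
    sample_rate: float | None = None,
) -> SignalRecord:
    """Read a waveform from disk.

    ``sample_rate`` is taken from the WAV header for ``wav16``; for the
    headerless formats it defaults to 2000 Hz unless given explicitly.
    """
    path = Path(path)
    if fmt not in FORMATS:
        raise ParameterError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt == "wav16":
        try:
            rate, data = wavfile.read(str(path))
        except ValueError as exc:
            raise FormatError(f"cannot parse WAV file {path}: {exc}") from exc
        if data.ndim != 1:
            raise FormatError("multi-channel WAV input is not supported")
        if data.dtype != np.int16:
            raise FormatError(
                f"expected 16-bit PCM WAV, got dtype {data.dtype}"
            )
        return SignalRecord(data.astype(np.int64), float(rate), 16)

    rate = float(sample_rate) if sample_rate is not None else DEFAULT_SAMPLE_RATE
    if fmt == "raw_int16":
        raw = path.read_bytes()
        if len(raw) % 2:
            raise FormatError("raw_int16 file has an odd byte count")
        data = np.frombuffer(raw, dtype="<i2").astype(np.int64)
        return SignalRecord(data, rate, 16)

    # text: one numeric value per line
    values: list[int] = []
    lo, hi = _int_bounds(16)
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            v = int(line)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: not an integer: {line!r}") from exc
        if not lo <= v <= hi:
            raise ParameterError(f"{path}:{lineno}: value {v} outside int16 range")
        values.append(v)
    return SignalRecord(np.asarray(values, dtype=np.int64), rate, 16)


def write_signal(record: SignalRecord, path: str | Path, fmt: str = "wav16") -> None:
    """Write a waveform; the file reads back sample-identical via read_signal."""
    path = Path(path)
    if fmt not in FORMATS:
        raise ParameterError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    lo, hi = _int_bounds(16)
    if record.samples.size and (record.samples.min() < lo or record.samples.max() > hi):
        raise ParameterError("samples outside int16 range cannot be written")

    if fmt == "wav16":
        wavfile.write(str(path), int(round(record.sample_rate)),
                      record.samples.astype(np.int16))
    elif fmt == "raw_int16":
        path.write_bytes(record.samples.astype("<i2").tobytes())
    else:
        path.write_text("".join(f"{int(v)}\n" for v in record.samples))


def segment(record: SignalRecord, window_length: int) -> WindowSet:
    """Cut the signal into consecutive length-N windows, zero-padding the last.

    ``window_length`` must be a power of two (dyadic wavelet decomposition
    requires it downstream).
    """
    n = int(window_length)
    if n < 1 or (n & (n - 1)):
        raise ParameterError(f"window_length must be a power of two, got {n}")
    k = record.length
    if k == 0:
        return WindowSet(np.empty((0, n), dtype=np.int64), 0, 0,
                         record.sample_rate, record.bit_depth)
    n_windows = -(-k // n)
    pad = n_windows * n - k
    padded = np.zeros(n_windows * n, dtype=np.int64)
    padded[:k] = record.samples
    return WindowSet(padded.reshape(n_windows, n), k, pad,
                     record.sample_rate, record.bit_depth)


def reassemble(windows: WindowSet) -> SignalRecord:
    """Concatenate windows and truncate the zero padding: inverse of segment."""
    if windows.n_windows == 0:
        return SignalRecord(np.empty(0, dtype=np.int64),
                            windows.sample_rate, windows.bit_depth)
    n = windows.window_length
    expected = windows.n_windows * n - windows.pad_count
    if expected != windows.original_length:
        raise FormatError(
            f"window count x length - pad ({expected}) does not match "
            f"original_length ({windows.original_length})"
        )
    flat = windows.windows.reshape(-1)[: windows.original_length]
    return SignalRecord(flat.copy(), windows.sample_rate, windows.bit_depth)
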