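"""Compress/decompress orchestration and the packed ``.semgz`` file format.

The container is fully self-describing: a fixed little-endian header carries
everything the decoder needs (sampling metadata, window geometry, wavelet,
allocation shape and its parameters), protected by a CRC-32; each window's
arithmetic-coded payload follows with a 4-byte length prefix.  The reported
compressed size C_S is the whole file, header included.

Header layout (little-endian)::

    offset  size  field
    0       4     magic  b"SEMG"
    4       1     format version (1)
    5       8     sample_rate, float64 Hz
    13      1     bit depth R
    14      8     original length K, uint64
    22      4     window length N, uint32
    26      2     sub-band count M, uint16
    28      1     decomposition levels
    29      8     wavelet name, ASCII padded with NUL
    37      1     shape id (index into allocation.SHAPES)
    38      1     Q   39  1  L
    40      4     alpha, float32      44  4  beta, float32
    48      4     window count, uint32
    52      4     pad count, uint32
    56      4     CRC-32 of bytes 0..55
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import entropy
from .allocation import SHAPES, allocate
from .errors import DecodeError, FormatError, ParameterError
from .quantizer import QuantizedWindow, dequantize, quantize
from .signal_io import SignalRecord, WindowSet, reassemble, segment
from .transform import forward_dwt, inverse_dwt, round_to_integer

__all__ = ["CodecConfig", "CompressedStream", "compress", "decompress",
           "compress_file", "decompress_file"]

MAGIC = b"SEMG"
VERSION = 1
_HEADER_FMT = "<4sBdBQIHB8sBBBffII"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT) + 4  # + CRC32


@dataclass(frozen=True)
class CodecConfig:
    """Complete codec configuration; defaults match the standard operating
    point (2048-sample windows, 16 sub-bands, db4/8-level wavelet)."""

    window_length: int = 2048          # N
    sub_bands: int = 16                # M
    wavelet: str = "db4"
    levels: int = 8
    shape: str = "rht"
    q_bits: int = 10                   # Q, bits for the lowest sub-band
    l_bits: int = 2                    # L, bits for the highest sub-band
    alpha: float = 0.4                 # RHT transition steepness
    beta: float = 0.5                  # RHT midpoint fraction

    def validate(self) -> "CodecConfig":
        n, m = self.window_length, self.sub_bands
        if n < 1 or (n & (n - 1)):
            raise ParameterError(f"window length N={n} must be a power of two")
        if m < 2 or n % m:
            raise ParameterError(f"sub-band count M={m} must divide N={n}")
        if self.levels < 1 or n % (1 << self.levels):
            raise ParameterError(
                f"2**levels = {1 << self.levels} must divide N={n}"
            )
        if self.shape.lower() not in SHAPES:
            raise ParameterError(f"shape must be one of {SHAPES}")
        if len(self.wavelet.encode()) > 8:
            raise ParameterError("wavelet name longer than 8 bytes")
        # raises on bad (Q, L, alpha, beta) combinations for the shape
        allocate(self.shape, self.q_bits, self.l_bits, m, self.alpha, self.beta)
        return self


@dataclass(frozen=True)
class CompressedStream:
    """Parsed in-memory form of one ``.semgz`` file."""

    config: CodecConfig
    sample_rate: float
    bit_depth: int
    original_length: int
    pad_count: int
    payloads: tuple[bytes, ...]

    @property
    def n_windows(self) -> int:
        return len(self.payloads)

    @property
    def total_size_bytes(self) -> int:
        """C_S: on-disk size in bytes, header plus framed payloads."""
        return _HEADER_SIZE + sum(4 + len(p) for p in self.payloads)

    def to_bytes(self) -> bytes:
        c = self.config
        head = struct.pack(
            _HEADER_FMT, MAGIC, VERSION, self.sample_rate, self.bit_depth,
            self.original_length, c.window_length, c.sub_bands, c.levels,
            c.wavelet.encode().ljust(8, b"\0"),
            SHAPES.index(c.shape.lower()), c.q_bits, c.l_bits,
            c.alpha, c.beta, self.n_windows, self.pad_count,
        )
        head += struct.pack("<I", zlib.crc32(head) & 0xFFFFFFFF)
        parts = [head]
        for p in self.payloads:
            parts.append(struct.pack("<I", len(p)))
            parts.append(p)
        return b"".join(parts)

    @classmethod
    def from_bytes(cls, data: bytes) -> "CompressedStream":
        if len(data) < _HEADER_SIZE:
            raise FormatError("stream shorter than the fixed header")
        head = data[: _HEADER_SIZE - 4]
        (magic, version, rate, r_bits, k_len, n, m, levels, wav, shape_id,
         q, l, alpha, beta, n_windows, pad) = struct.unpack(_HEADER_FMT, head)
        (crc,) = struct.unpack_from("<I", data, _HEADER_SIZE - 4)
        if magic != MAGIC:
            raise FormatError(f"bad magic {magic!r}; not a .semgz stream")
        if version != VERSION:
            raise FormatError(f"unsupported format version {version}")
        if crc != (zlib.crc32(head) & 0xFFFFFFFF):
            raise FormatError("header CRC mismatch")
        if shape_id >= len(SHAPES):
            raise FormatError(f"unknown shape id {shape_id}")
        config = CodecConfig(
            window_length=n, sub_bands=m,
            wavelet=wav.rstrip(b"\0").decode(), levels=levels,
            shape=SHAPES[shape_id], q_bits=q, l_bits=l,
            alpha=float(alpha), beta=float(beta),
        )
        payloads = []
        pos = _HEADER_SIZE
        for _ in range(n_windows):
            if pos + 4 > len(data):
                raise FormatError("stream truncated in a window length prefix")
            (plen,) = struct.unpack_from("<I", data, pos)
            pos += 4
            if pos + plen > len(data):
                raise FormatError("stream truncated inside a window payload")
            payloads.append(data[pos : pos + plen])
            pos += plen
        if pos != len(data):
            raise FormatError(f"{len(data) - pos} trailing bytes after payloads")
        return cls(config, rate, r_bits, k_len, pad, tuple(payloads))


def compress(record: SignalRecord, config: CodecConfig | None = None) -> CompressedStream:
    """Run the full encoder pipeline: segment, DWT, quantize, entropy-code."""
    config = (config or CodecConfig()).validate()
    # the header stores alpha/beta as float32; normalize up front so the
    # in-memory stream equals its parsed on-disk form bit for bit
    config = replace(config,
                     alpha=float(np.float32(config.alpha)),
                     beta=float(np.float32(config.beta)))
    windows = segment(record, config.window_length)
    plan = allocate(config.shape, config.q_bits, config.l_bits,
                    config.sub_bands, config.alpha, config.beta)
    widths = entropy.widths_for_plan(plan, config.window_length)
    payloads = []
    for win in windows.windows:
        coeffs = forward_dwt(win, config.wavelet, config.levels)
        qwin = quantize(coeffs, plan, record.bit_depth)
        payloads.append(entropy.encode(entropy.SymbolStream(qwin.symbols, widths)))
    return CompressedStream(config, record.sample_rate, record.bit_depth,
                            record.length, windows.pad_count, tuple(payloads))


def decompress(stream: CompressedStream) -> SignalRecord:
    """Run the decoder pipeline; uses only information carried by the stream."""
    c = stream.config.validate()
    plan = allocate(c.shape, c.q_bits, c.l_bits, c.sub_bands, c.alpha, c.beta)
    widths = entropy.widths_for_plan(plan, c.window_length)
    decoded = np.empty((stream.n_windows, c.window_length), dtype=np.float64)
    for i, payload in enumerate(stream.payloads):
        symbols = entropy.decode(payload, widths).symbols
        qwin = QuantizedWindow(symbols, plan, stream.bit_depth)
        coeffs = dequantize(qwin, c.levels, c.wavelet)
        decoded[i] = inverse_dwt(coeffs)
    flat = decoded.reshape(-1)[: stream.original_length]
    samples = round_to_integer(flat, stream.bit_depth)
    return SignalRecord(samples, stream.sample_rate, stream.bit_depth)


def compress_file(in_path: str | Path, out_path: str | Path,
                  config: CodecConfig | None = None, fmt: str = "wav16",
                  sample_rate: float | None = None) -> CompressedStream:
    from .signal_io import read_signal

    record = read_signal(in_path, fmt, sample_rate)
    stream = compress(record, config)
    Path(out_path).write_bytes(stream.to_bytes())
    return stream


def decompress_file(in_path: str | Path, out_path: str | Path,
                    fmt: str = "wav16") -> SignalRecord:
    from .signal_io import write_signal

    stream = CompressedStream.from_bytes(Path(in_path).read_bytes())
    record = decompress(stream)
    write_signal(record, out_path, fmt)
    return record
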