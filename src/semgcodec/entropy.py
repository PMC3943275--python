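"""Lossless adaptive arithmetic coding of the quantized-symbol stream.

The quantized coefficients of one window form a symbol sequence in which
position ``k`` draws from the alphabet ``{-lambda_m, ..., +lambda_m}`` of its
sub-band (size ``2*lambda_m + 1``).  Sub-bands sharing a bit width ``B``
share one adaptive order-0 frequency model, so alphabet statistics are
pooled where the alphabets coincide and no frequency tables are ever
transmitted.  Each window is coded independently (models reset), so windows
are individually decodable.

The coder is a classic integer arithmetic coder with 32-bit code values and
underflow-bit handling.  Models keep per-symbol counts in a Fenwick tree
(O(log A) cumulative-frequency queries and symbol search); counts start at 1
(Laplace prior), grow by an increment of 32 per occurrence for fast
adaptation, and are halved when the total hits a ceiling.  A CRC-32 of the
symbol vector is appended through a fixed uniform byte model, so truncated
or corrupt payloads — or payloads decoded under the wrong allocation plan —
raise ``DecodeError`` instead of yielding silent garbage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .allocation import AllocationPlan
from .errors import DecodeError, ParameterError

__all__ = ["SymbolStream", "widths_for_plan", "encode", "decode"]

_FULL = 1 << 32
_HALF = _FULL >> 1
_QTR = _FULL >> 2
_3QTR = _HALF + _QTR

_INCREMENT = 32       # count added per symbol occurrence (fast adaptation)
_COUNT_CEILING = 1 << 24   # halve counts when a model's total reaches this
_MAX_OVERRUN_BITS = 64     # slack the decoder may read past the payload


@dataclass(frozen=True)
class SymbolStream:
    """Symbols plus the per-position sub-band bit width (the model context)."""

    symbols: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=np.int64)
        w = np.asarray(self.widths, dtype=np.int64)
        if s.shape != w.shape or s.ndim != 1:
            raise ParameterError("symbols and widths must be equal-length 1-D")
        lam = (1 << w.astype(np.int64))
        if s.size and np.any(np.abs(s) > lam):
            raise ParameterError("symbol outside its context alphabet")
        object.__setattr__(self, "symbols", s)
        object.__setattr__(self, "widths", w)


def widths_for_plan(plan: AllocationPlan, n: int) -> np.ndarray:
    """Per-coefficient context width B[m(k)] for a length-n window."""
    if n % plan.sub_band_count:
        raise ParameterError(
            f"M={plan.sub_band_count} does not divide N={n}"
        )
    return np.repeat(plan.bits, n // plan.sub_band_count)


class _Model:
    """Adaptive frequency model over alphabet {0..size-1}, Fenwick-backed."""

    __slots__ = ("size", "tree", "counts", "total", "topbit")

    def __init__(self, size: int) -> None:
        self.size = size
        self.counts = [1] * size
        tree = [0] * (size + 1)
        for i in range(1, size + 1):
            tree[i] = i & -i   # Fenwick tree of all-ones counts
        self.tree = tree
        self.total = size
        top = 1
        while top * 2 <= size:
            top *= 2
        self.topbit = top

    def prefix(self, i: int) -> int:
        """Sum of counts[0..i-1]."""
        s = 0
        tree = self.tree
        while i:
            s += tree[i]
            i -= i & -i
        return s

    def update(self, sym: int) -> None:
        self.counts[sym] += _INCREMENT
        i = sym + 1
        tree = self.tree
        n = self.size
        while i <= n:
            tree[i] += _INCREMENT
            i += i & -i
        self.total += _INCREMENT
        if self.total >= _COUNT_CEILING:
            self._halve()

    def _halve(self) -> None:
        counts = [max(1, c >> 1) for c in self.counts]
        self.counts = counts
        tree = [0] * (self.size + 1)
        for i, c in enumerate(counts, 1):
            tree[i] += c
            j = i + (i & -i)
            if j <= self.size:
                tree[j] += tree[i]
        self.tree = tree
        self.total = sum(counts)

    def locate(self, target: int) -> tuple[int, int, int]:
        """Find (symbol, cum_below, count) with cum_below <= target < cum+count."""
        pos = 0
        rem = target
        bit = self.topbit
        tree = self.tree
        n = self.size
        while bit:
            nxt = pos + bit
            if nxt <= n and tree[nxt] <= rem:
                pos = nxt
                rem -= tree[nxt]
            bit >>= 1
        return pos, target - rem, self.counts[pos]


class _BitWriter:
    __slots__ = ("out", "acc", "nbits", "padding")

    def __init__(self) -> None:
        self.out = bytearray()
        self.acc = 0
        self.nbits = 0
        self.padding = 0   # zero bits appended by the final flush

    def write(self, bit: int) -> None:
        self.acc = (self.acc << 1) | bit
        self.nbits += 1
        if self.nbits == 8:
            self.out.append(self.acc)
            self.acc = 0
            self.nbits = 0

    def flush(self) -> bytes:
        if self.nbits:
            self.padding = 8 - self.nbits
            self.out.append(self.acc << self.padding)
            self.acc = 0
            self.nbits = 0
        return bytes(self.out)


class _BitReader:
    __slots__ = ("data", "pos", "overrun")

    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0
        self.overrun = 0

    def read(self) -> int:
        p = self.pos
        byte_i = p >> 3
        if byte_i >= len(self.data):
            self.overrun += 1
            if self.overrun > _MAX_OVERRUN_BITS:
                raise DecodeError("payload truncated: decoder ran out of bits")
            return 0
        self.pos = p + 1
        return (self.data[byte_i] >> (7 - (p & 7))) & 1


class _Encoder:
    __slots__ = ("low", "high", "pending", "bits")

    def __init__(self) -> None:
        self.low = 0
        self.high = _FULL - 1
        self.pending = 0
        self.bits = _BitWriter()

    def _emit(self, bit: int) -> None:
        w = self.bits.write
        w(bit)
        inv = 1 - bit
        for _ in range(self.pending):
            w(inv)
        self.pending = 0

    def encode(self, cum: int, freq: int, total: int) -> None:
        span = self.high - self.low + 1
        self.high = self.low + span * (cum + freq) // total - 1
        self.low = self.low + span * cum // total
        while True:
            if self.high < _HALF:
                self._emit(0)
            elif self.low >= _HALF:
                self._emit(1)
                self.low -= _HALF
                self.high -= _HALF
            elif self.low >= _QTR and self.high < _3QTR:
                self.pending += 1
                self.low -= _QTR
                self.high -= _QTR
            else:
                break
            self.low <<= 1
            self.high = (self.high << 1) | 1

    def finish(self) -> bytes:
        self.pending += 1
        self._emit(0 if self.low < _QTR else 1)
        return self.bits.flush()


class _Decoder:
    __slots__ = ("low", "high", "value", "bits")

    def __init__(self, payload: bytes) -> None:
        self.low = 0
        self.high = _FULL - 1
        self.bits = _BitReader(payload)
        v = 0
        for _ in range(32):
            v = (v << 1) | self.bits.read()
        self.value = v

    def target(self, total: int) -> int:
        span = self.high - self.low + 1
        t = ((self.value - self.low + 1) * total - 1) // span
        if t < 0 or t >= total:
            raise DecodeError("corrupt payload: code value out of range")
        return t

    def consume(self, cum: int, freq: int, total: int) -> None:
        span = self.high - self.low + 1
        self.high = self.low + span * (cum + freq) // total - 1
        self.low = self.low + span * cum // total
        while True:
            if self.high < _HALF:
                pass
            elif self.low >= _HALF:
                self.low -= _HALF
                self.high -= _HALF
                self.value -= _HALF
            elif self.low >= _QTR and self.high < _3QTR:
                self.low -= _QTR
                self.high -= _QTR
                self.value -= _QTR
            else:
                break
            self.low <<= 1
            self.high = (self.high << 1) | 1
            self.value = (self.value << 1) | self.bits.read()


def _crc(symbols: np.ndarray) -> int:
    return zlib.crc32(np.ascontiguousarray(symbols, dtype="<i8").tobytes()) & 0xFFFFFFFF


def encode(stream: SymbolStream) -> bytes:
    """Encode a symbol stream to a self-checking byte payload."""
    symbols = stream.symbols
    widths = stream.widths
    enc = _Encoder()
    models: dict[int, _Model] = {}
    for sym, width in zip(symbols.tolist(), widths.tolist()):
        model = models.get(width)
        if model is None:
            model = _Model((1 << (width + 1)) + 1)   # 2*lambda + 1
            models[width] = model
        idx = sym + (1 << width)
        cum = model.prefix(idx)
        enc.encode(cum, model.counts[idx], model.total)
        model.update(idx)
    crc = _crc(symbols)
    for shift in (24, 16, 8, 0):   # fixed uniform byte model for the trailer
        byte = (crc >> shift) & 0xFF
        enc.encode(byte, 1, 256)
    body = enc.finish()
    # 4-byte bit-count frame: makes any payload length change detectable even
    # when the lost bits were flush padding the decoder never consumes
    nbits = 8 * len(body) - enc.bits.padding
    return nbits.to_bytes(4, "big") + body


def decode(payload: bytes, widths: np.ndarray, n: int | None = None) -> SymbolStream:
    """Exactly invert :func:`encode`; raises DecodeError on any inconsistency."""
    widths = np.asarray(widths, dtype=np.int64)
    if n is not None and n != widths.size:
        raise ParameterError("n does not match the widths vector length")
    if len(payload) < 4:
        raise DecodeError("payload too short for the bit-count frame")
    nbits = int.from_bytes(payload[:4], "big")
    body = payload[4:]
    if len(body) != (nbits + 7) // 8:
        raise DecodeError(
            f"payload length {len(body)} bytes inconsistent with the declared "
            f"{nbits} coded bits"
        )
    dec = _Decoder(body)
    models: dict[int, _Model] = {}
    out = np.empty(widths.size, dtype=np.int64)
    for i, width in enumerate(widths.tolist()):
        model = models.get(width)
        if model is None:
            model = _Model((1 << (width + 1)) + 1)
            models[width] = model
        idx, cum, freq = model.locate(dec.target(model.total))
        dec.consume(cum, freq, model.total)
        model.update(idx)
        out[i] = idx - (1 << width)
    crc = 0
    for _ in range(4):
        byte = dec.target(256)
        dec.consume(byte, 1, 256)
        crc = (crc << 8) | byte
    if crc != _crc(out):
        raise DecodeError("corrupt payload: symbol checksum mismatch")
    return SymbolStream(out, widths)
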