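import dataclasses

import numpy as np
import pytest

import semgcodec as sc
from semgcodec.errors import FormatError, ParameterError


@pytest.fixture(scope="module")
def short_record():
    return sc.generate(sc.SyntheticConfig(duration_s=2.0, seed=3))


class TestRoundTrip:
    def test_length_and_metadata_preserved(self, short_record):
        stream = sc.compress(short_record)
        back = sc.decompress(stream)
        assert back.length == short_record.length
        assert back.sample_rate == short_record.sample_rate
        assert back.bit_depth == 16

    def test_bytes_round_trip_is_exact(self, short_record):
        stream = sc.compress(short_record)
        parsed = sc.CompressedStream.from_bytes(stream.to_bytes())
        assert parsed.config == stream.config
        assert parsed.payloads == stream.payloads
        assert np.array_equal(sc.decompress(parsed).samples,
                              sc.decompress(stream).samples)

    def test_determinism(self, short_record):
        a = sc.compress(short_record).to_bytes()
        b = sc.compress(short_record).to_bytes()
        assert a == b

    def test_window_record_count(self):
        rec = sc.SignalRecord(
            (np.arange(4096) % 201 - 100).astype(np.int64))
        stream = sc.compress(rec)
        assert stream.n_windows == 2
        assert stream.pad_count == 0

    def test_empty_signal(self):
        rec = sc.SignalRecord(np.empty(0, dtype=np.int64))
        stream = sc.compress(rec)
        assert stream.n_windows == 0
        data = stream.to_bytes()
        assert len(data) == stream.total_size_bytes
        assert sc.decompress(sc.CompressedStream.from_bytes(data)).length == 0

    def test_near_lossless_limit(self, short_record):
        cfg = sc.CodecConfig(shape="dla", q_bits=15, l_bits=15)
        back = sc.decompress(sc.compress(short_record, cfg))
        assert sc.percent_residual_difference(short_record, back) < 0.1

    def test_sample_rate_is_metadata_only(self, short_record):
        stream = sc.compress(short_record)
        tampered = dataclasses.replace(stream, sample_rate=9999.0)
        assert np.array_equal(sc.decompress(tampered).samples,
                              sc.decompress(stream).samples)

    @pytest.mark.parametrize("shape", sc.SHAPES)
    def test_stream_is_self_describing(self, short_record, shape):
        cfg = sc.CodecConfig(shape=shape, q_bits=9, l_bits=2)
        data = sc.compress(short_record, cfg).to_bytes()
        # decoding uses only the bytes; config is recovered from the header
        parsed = sc.CompressedStream.from_bytes(data)
        assert parsed.config.shape == shape
        assert sc.decompress(parsed).length == short_record.length


class TestFormatErrors:
    def test_bad_magic(self, short_record):
        data = bytearray(sc.compress(short_record).to_bytes())
        data[0] = ord(b"X")
        with pytest.raises(FormatError):
            sc.CompressedStream.from_bytes(bytes(data))

    def test_header_crc(self, short_record):
        data = bytearray(sc.compress(short_record).to_bytes())
        data[20] ^= 0xFF
        with pytest.raises(FormatError):
            sc.CompressedStream.from_bytes(bytes(data))

    def test_truncated_stream(self, short_record):
        data = sc.compress(short_record).to_bytes()
        with pytest.raises(FormatError):
            sc.CompressedStream.from_bytes(data[:-3])

    def test_trailing_garbage(self, short_record):
        data = sc.compress(short_record).to_bytes() + b"xx"
        with pytest.raises(FormatError):
            sc.CompressedStream.from_bytes(data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            sc.CodecConfig(window_length=2048, sub_bands=15).validate()
        with pytest.raises(ParameterError):
            sc.CodecConfig(window_length=1000).validate()
        with pytest.raises(ParameterError):
            sc.CodecConfig(shape="dea", l_bits=1).validate()


class TestSizeAccounting:
    def test_reported_size_matches_disk(self, tmp_path, short_record):
        f = tmp_path / "x.semgz"
        stream = sc.compress(short_record)
        f.write_bytes(stream.to_bytes())
        assert f.stat().st_size == stream.total_size_bytes

    def test_file_level_helpers(self, tmp_path, short_record):
        wav = tmp_path / "in.wav"
        sc.write_signal(short_record, wav, "wav16")
        packed = tmp_path / "x.semgz"
        out = tmp_path / "out.wav"
        sc.compress_file(wav, packed)
        sc.decompress_file(packed, out)
        assert sc.read_signal(out).length == short_record.length
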