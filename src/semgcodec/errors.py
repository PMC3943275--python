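"""Exception hierarchy shared across the codec stages."""


class SemgCodecError(Exception):
    """Base class for all codec errors."""


class ParameterError(SemgCodecError, ValueError):
    """An argument violates a stage's contract (range, divisibility, shape)."""


class FormatError(SemgCodecError, ValueError):
    """A file or stream does not parse in the stated format."""


class DecodeError(SemgCodecError, ValueError):
    """A compressed payload is truncated, corrupt, or inconsistent."""
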