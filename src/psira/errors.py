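"""Exception hierarchy for psira."""


class PsiraError(Exception):
    """Base class for all psira errors."""


class EncodingError(PsiraError, ValueError):
    """Reference or query sequence cannot be 2-bit encoded."""


class ParameterError(PsiraError, ValueError):
    """An index or search parameter is out of its valid range."""


class PatternError(PsiraError, ValueError):
    """A query pattern violates a search precondition."""


class AmbiguousBaseError(PatternError):
    """A query pattern contains a non-ACGT base under the reject policy."""


class IndexFormatError(PsiraError, ValueError):
    """A serialized index blob cannot be decoded."""


class BadMagicError(IndexFormatError):
    """The blob does not start with the expected magic bytes."""


class UnsupportedVersionError(IndexFormatError):
    """The blob declares a format version this build cannot read."""


class TruncatedIndexError(IndexFormatError):
    """The blob ends before all declared sections are present."""
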