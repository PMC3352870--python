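"""Exception hierarchy for the ONH quantification pipeline.

Each error class maps to a distinct CLI exit code so batch callers can
distinguish bad inputs from algorithmic failures.
"""


class OnhQuantError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class MetadataError(OnhQuantError):
    """Missing, contradictory or inconsistent volume metadata."""

    exit_code = 2


class FormatError(OnhQuantError):
    """Malformed container (ragged pages, wrong byte count, unknown dtype)."""

    exit_code = 3


class ParameterError(OnhQuantError):
    """Invalid algorithm or phantom parameter."""

    exit_code = 4


class SegmentationError(OnhQuantError):
    """Layer detection failed on a B-scan (too dark, ILM coverage too low...)."""

    exit_code = 5


class QuantificationError(OnhQuantError):
    """Volume-level quantification unreliable (too many flagged B-scans)."""

    exit_code = 6


class ValidationError(OnhQuantError):
    """A domain object violates its invariants."""

    exit_code = 7
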