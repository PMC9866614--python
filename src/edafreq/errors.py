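"""Typed errors raised by the pipeline.

Every anticipated failure mode gets its own class so callers can decide
per-segment policy (e.g. drop zero-energy segments) without string matching.
"""


class EdaFreqError(Exception):
    """Base class for all errors raised by edafreq."""


class MalformedRecordError(EdaFreqError):
    """A subject record is missing a required channel or is structurally wrong."""


class SchemaError(EdaFreqError):
    """Feature-table rows disagree on their feature-name set."""


class EmptyBandError(EdaFreqError):
    """A frequency band contains no (or too few) spectrum bins."""


class ZeroEnergySegmentError(EdaFreqError):
    """A segment's spectrum carries no energy; energy-based features are undefined."""
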