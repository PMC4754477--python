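"""Exception hierarchy for wafecg.

Every error raised by the library derives from :class:`WafecgError` so callers
can catch the whole family with one clause.
"""


class WafecgError(Exception):
    """Base class for all wafecg errors."""


class FormatError(WafecgError):
    """A file could not be parsed; the message names the offending field."""


class LeadNotFoundError(WafecgError):
    """The requested ECG lead is not present in the record."""


class DegenerateSignalError(WafecgError):
    """A signal (or frame) carries no energy where nonzero energy is required."""


class DecompositionError(WafecgError):
    """The segment is too short for the requested wavelet-packet depth."""


class IncompatibleFeaturesError(WafecgError):
    """Feature vectors with mixed extractors, configs or lengths were combined."""


class UndefinedScoreError(WafecgError):
    """A confirmation score is undefined for the given operands."""


class UndefinedMeasureError(WafecgError):
    """A performance measure has a zero denominator; the message names it."""


class ConfigError(WafecgError):
    """A run configuration contains invalid fields; the message lists them all."""
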