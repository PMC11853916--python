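"""Exception hierarchy for perimark.

All errors raised by the library derive from :class:`PerimarkError`, so
callers can catch one base class. ``FormatError`` covers malformed input
files (duplicate identifiers, bad schema); ``ValidationError`` covers
semantically invalid values (negative abundances, unknown group tokens,
inconsistent shapes).
"""


class PerimarkError(Exception):
    """Base class for all perimark errors."""


class FormatError(PerimarkError):
    """Malformed input file: bad schema, duplicated identifiers."""


class ValidationError(PerimarkError):
    """Semantically invalid value or inconsistent inputs."""


class DegenerateSampleError(ValidationError):
    """A sample with all-zero abundances cannot be ppm-normalized."""


class UndefinedMetricError(PerimarkError):
    """A performance metric with a zero denominator (e.g. no positives)."""


class SplitError(PerimarkError):
    """A train/test split left one group empty."""
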