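"""Exception hierarchy for shrubring.

All package-specific errors derive from :class:`ShrubRingError` so callers
can catch the whole family with one clause.
"""


class ShrubRingError(Exception):
    """Base class for all shrubring errors."""


class FormatError(ShrubRingError):
    """Malformed input file (Tucson .rwl or delimited table).

    Carries an optional 1-based line number of the offending line.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class NamingError(ShrubRingError):
    """Series identifier cannot be encoded in the requested output format."""


class AlignmentError(ShrubRingError):
    """Series do not share the year support required by the operation."""


class OverlapError(ShrubRingError):
    """Pairwise overlap between series is too short for the statistic."""


class LengthError(ShrubRingError):
    """Series is too short for the requested operation."""


class DegenerateSeriesError(ShrubRingError):
    """Series carries no usable signal (e.g. all widths zero)."""


class IntervalError(ShrubRingError):
    """Invalid or uncovered calendar-year interval."""


class SampleSizeError(ShrubRingError):
    """Too few replicates (shoots, series) for the requested test."""


class ParameterError(ShrubRingError):
    """Inconsistent simulation or configuration parameters."""
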