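"""Exception hierarchy for the ignidyn pipeline.

Every error raised by the package derives from :class:`IgnidynError` so
callers (and the CLI) can catch pipeline failures in one place.
"""


class IgnidynError(Exception):
    """Base class for all ignidyn errors."""


class FormatError(IgnidynError):
    """A file does not conform to the expected tabular layout (e.g. ragged rows)."""


class DataError(IgnidynError):
    """A table cell is missing or non-numeric; the message names its coordinates."""


class AlignmentError(IgnidynError):
    """Region identifiers do not align between two tables; lists the offenders."""


class ParameterError(IgnidynError):
    """A configuration or call parameter is outside its valid range."""


class DegenerateSignalError(IgnidynError):
    """A signal has no temporal variance where variance is required."""


class ContractError(IgnidynError):
    """An internal contract was violated (non-square adjacency, length mismatch...)."""


class ConvergenceError(IgnidynError):
    """A model fit failed to converge; carries diagnostic information."""
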