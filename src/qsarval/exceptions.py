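"""Exception hierarchy.

All toolkit errors derive from :class:`QsarvalError` so callers can catch one
type at the CLI boundary.
"""


class QsarvalError(Exception):
    """Base class for all qsarval errors."""


class InsufficientDataError(QsarvalError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(QsarvalError):
    """Input is structurally valid but degenerate (constant vector, zero
    sum of squares, non-positive range) for the requested statistic."""


class SchemaError(QsarvalError):
    """Input file does not match the expected column/value schema."""


class UsageError(QsarvalError):
    """A parameter value outside its documented domain."""
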