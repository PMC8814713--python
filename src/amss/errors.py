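"""Exception hierarchy.

All package errors derive from :class:`AmssError` so callers (notably the
CLI) can distinguish user/data problems from internal bugs.
"""


class AmssError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AmssError):
    """A cell in an input file could not be parsed; names row and column."""


class ValidationError(AmssError):
    """Input violates a domain contract (range, duplicate, schema...)."""


class UndefinedValueError(AmssError):
    """A derived quantity is undefined because a required input is missing."""


class DegenerateDataError(AmssError):
    """A statistical routine received data it cannot decompose
    (e.g. zero within-cell variance in an ANOVA)."""
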