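"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError and ValidationError
exit 2, IOFormatError exits 3, ComputationError exits 4.
"""


class NetpharmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NetpharmError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(NetpharmError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A table is missing a required column or has a malformed cell."""


class IOFormatError(NetpharmError):
    """A file could not be parsed or written; message carries line numbers."""


class FixtureLookupError(NetpharmError, LookupError):
    """Unknown built-in fixture name; message lists the valid names."""


class ComputationError(NetpharmError):
    """A computation cannot proceed (non-graphical sequence, fit on too few
    points, empty background, ...)."""


class DomainError(ComputationError):
    """Arguments outside the mathematical domain of an operation."""


class FitError(ComputationError):
    """Too few points, or degenerate data, for a model fit."""


class NonGraphicalSequenceError(ComputationError):
    """Degree sequence fails the Erdős–Gallai conditions."""
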