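"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes, so analysis code should raise
the most specific class that applies.
"""


class CycloFitError(Exception):
    """Base class for all package errors."""


class ValidationError(CycloFitError, ValueError):
    """Input data violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file could not be parsed in the declared dialect."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class DomainError(ValidationError):
    """A scalar argument is outside the mathematical domain of a formula."""


class NumericalError(CycloFitError, RuntimeError):
    """An iterative procedure failed to converge."""
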