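"""Exception hierarchy.

All package errors derive from :class:`PathmixError` so callers can catch
one base class; the subclasses distinguish configuration mistakes, malformed
input files, numerical failures, and contract violations between pipeline
stages.
"""


class PathmixError(Exception):
    """Base class for all errors raised by pathmix."""


class ConfigError(PathmixError):
    """A run or reader configuration is invalid (e.g. a mapped column is missing)."""


class FormatError(PathmixError):
    """An input file violates its format contract; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateInputError(PathmixError):
    """Input is syntactically valid but carries no usable signal (e.g. constant y)."""


class NumericalError(PathmixError):
    """A linear system could not be solved (singular covariance after jitter)."""


class ContractError(PathmixError):
    """Objects passed between stages do not conform (dimension/label mismatch)."""
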