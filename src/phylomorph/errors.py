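"""Exception hierarchy shared across the package.

``ValidationError`` covers bad inputs and file-format problems (CLI exit
code 2); ``NumericalError`` covers failures of the numerical machinery
such as singular covariance matrices (CLI exit code 3).
"""


class PhylomorphError(Exception):
    """Base class for all package errors."""


class ValidationError(PhylomorphError, ValueError):
    """Invalid user input: bad values, mismatched taxa, malformed files."""


class FormatError(ValidationError):
    """A file could not be parsed in the declared dialect."""


class NumericalError(PhylomorphError, ArithmeticError):
    """A numerical operation failed (singular matrix, no convergence...)."""
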