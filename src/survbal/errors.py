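"""Exception hierarchy shared across the package.

Exit-code convention for the CLI: validation problems exit with 2,
numerical failures with 3.
"""


class SurvbalError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(SurvbalError):
    """Bad inputs: missing columns, domain violations, impossible settings."""

    exit_code = 2


class NumericalError(SurvbalError):
    """Optimization or linear-algebra failure that prevents a result."""

    exit_code = 3
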