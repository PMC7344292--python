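"""Exception hierarchy.

Validation failures (bad shapes, invalid parameters, inconsistent IDs) raise
:class:`ValidationError`; optimizer blow-ups and other numerical failures
raise :class:`NumericalError`. The CLI maps these to exit codes 2 and 3.
"""


class ConfactError(Exception):
    """Base class for all package errors."""


class ValidationError(ConfactError, ValueError):
    """Invalid input data or parameters."""


class NumericalError(ConfactError, ArithmeticError):
    """A numerical procedure failed to produce a finite result."""
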