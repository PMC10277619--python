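"""Exception hierarchy.

``SchemaError`` maps to CLI exit code 2, ``NumericalError`` (and subclasses)
to exit code 3; everything derives from ``BiodesulfError`` so callers can
catch the whole family.
"""


class BiodesulfError(Exception):
    """Base class for all package errors."""


class DomainError(BiodesulfError, ValueError):
    """An input is outside the physically meaningful domain."""


class InvalidDesignError(BiodesulfError, ValueError):
    """A factorial design does not satisfy the L16(4^4) structure."""


class IncompleteDataError(BiodesulfError, ValueError):
    """Required observations are missing."""


class SchemaError(BiodesulfError, ValueError):
    """A tabular input does not match the declared column schema."""


class NumericalError(BiodesulfError, RuntimeError):
    """A numerical procedure failed (integration, inversion, regression)."""


class IntegrationError(NumericalError):
    """ODE or quadrature failure, with solver diagnostics in the message."""


class InversionError(NumericalError):
    """Root bracketing for t(x) inversion failed (non-monotone t(x))."""


class SingularDesignError(NumericalError):
    """Regression design matrix is rank deficient (e.g. constant x)."""


class FitError(NumericalError):
    """Nonlinear fit did not converge; carries the best-so-far estimate."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best
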