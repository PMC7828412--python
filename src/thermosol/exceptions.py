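"""Exception hierarchy for thermosol.

All errors derive from :class:`ThermosolError` so callers can catch the
package's failures with a single ``except`` clause; the concrete classes
distinguish bad inputs from fitting problems.
"""


class ThermosolError(Exception):
    """Base class for all thermosol errors."""


class InvalidInputError(ThermosolError, ValueError):
    """An argument violates a documented precondition (sign, range, shape)."""


class InsufficientDataError(ThermosolError, ValueError):
    """Too few observations to identify the requested model."""


class OutOfDomainError(ThermosolError, ValueError):
    """Evaluation requested outside a model's physical domain (e.g. T > Tm)."""


class FitFailureError(ThermosolError, RuntimeError):
    """A nonlinear optimiser failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDesignError(ThermosolError, ValueError):
    """A regression design matrix is rank deficient."""


class WrongModelError(ThermosolError, ValueError):
    """A model of the wrong kind was passed (e.g. mixture model to a
    single-solvent generator)."""
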