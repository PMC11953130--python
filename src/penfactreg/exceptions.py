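"""Exception hierarchy for penfactreg.

All package errors derive from :class:`PenFactRegError` so callers (and the
CLI) can catch one base class.
"""


class PenFactRegError(Exception):
    """Base class for all penfactreg errors."""


class SchemaError(PenFactRegError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(PenFactRegError):
    """An input table violates a domain invariant (duplicates, missing cells...)."""


class DegenerateDesignError(PenFactRegError):
    """The design matrix cannot be built (single genotype/environment, zero-variance EC...)."""


class RankDeficiencyError(PenFactRegError):
    """An unpenalized least-squares fit was requested on a rank-deficient design."""


class ConvergenceError(PenFactRegError):
    """The coordinate-descent solver did not converge within the iteration budget."""

    def __init__(self, message: str, lam: float | None = None, kkt_residual: float | None = None):
        super().__init__(message)
        self.lam = lam
        self.kkt_residual = kkt_residual


class GoEnViolationError(PenFactRegError):
    """A prediction was requested for a genotype not present in training.

    Reaction-norm parameters are estimated per genotype, so predictions for
    unseen genotypes require the two-stage marker model (``baselines``).
    """


class UnsupportedModeError(PenFactRegError):
    """An operation was requested in an EC mode it does not support."""
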