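"""Exception hierarchy shared across formsim modules."""


class FormsimError(Exception):
    """Base class for all formsim errors."""


class InvalidParameterError(FormsimError, ValueError):
    """A model parameter is non-finite or outside its admissible range."""


class FitFailureError(FormsimError, RuntimeError):
    """Nonlinear fit did not converge; carries the best candidate found."""

    def __init__(self, message, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate


class InsufficientDataError(FormsimError, ValueError):
    """Too few points / replicates for the requested computation."""


class UnsupportedDesignError(FormsimError, ValueError):
    """Experimental design outside what the package supports."""


class SingularDesignError(FormsimError, ValueError):
    """Rank-deficient design matrix."""


class OptimizationFailureError(FormsimError, RuntimeError):
    """All optimization starts failed."""


class SimulationIntegrityError(FormsimError, RuntimeError):
    """ODE solver failure or mass-balance violation in the absorption model."""


class InvalidObservationError(FormsimError, ValueError):
    """Observed PK values unusable (zero or negative)."""


class TrialInvalidError(FormsimError, RuntimeError):
    """A virtual crossover trial could not be completed for some subjects."""

    def __init__(self, message, failed_subjects=()):
        super().__init__(message)
        self.failed_subjects = list(failed_subjects)


class ConfigError(FormsimError, ValueError):
    """Bad or missing pipeline/stage configuration."""
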