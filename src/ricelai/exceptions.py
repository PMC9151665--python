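"""Exception hierarchy shared across the package."""


class RiceLAIError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RiceLAIError, ValueError):
    """Malformed or out-of-contract input data."""


class UndefinedStatisticError(RiceLAIError, ValueError):
    """A statistic is mathematically undefined for the given data
    (e.g. Nash-Sutcliffe efficiency when the observations have zero variance)."""


class InsufficientDataError(RiceLAIError, ValueError):
    """Too few data points to perform the operation."""


class ConfigError(RiceLAIError, ValueError):
    """Invalid configuration value or unknown configuration key."""


class OptimizerFailureError(RiceLAIError, RuntimeError):
    """The parameter optimizer encountered a non-finite objective.

    Carries ``last_good`` — the best (params, objective) pair seen before the
    failure — so callers can salvage a partial calibration.
    """

    def __init__(self, message, last_good=None):
        super().__init__(message)
        self.last_good = last_good


class TrainingFailureError(RiceLAIError, RuntimeError):
    """Regressor training diverged (non-finite loss)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
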