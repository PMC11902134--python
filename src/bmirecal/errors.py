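"""Exception hierarchy shared across the package."""


class BmirecalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BmirecalError, ValueError):
    """Invalid generator or pipeline configuration."""


class CohortParseError(BmirecalError, ValueError):
    """A cohort file could not be parsed or failed row validation."""


class DomainError(BmirecalError, ValueError):
    """An input value lies outside its physiologic/mathematical domain."""


class DegenerateTableError(BmirecalError, ValueError):
    """A contingency table is unusable for the requested statistic."""


class FitError(BmirecalError, ValueError):
    """Regression input is degenerate (too few points, constant predictor, ...)."""


class CutoffOrderingError(BmirecalError, ValueError):
    """Derived obesity cut-off does not exceed the overweight cut-off."""


class InversionError(BmirecalError, ValueError):
    """The log-polynomial cannot be inverted at the requested BMI."""


class ExtrapolationError(BmirecalError, ValueError):
    """A requested evaluation point lies beyond the extrapolation guard."""


class StageError(BmirecalError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted predictor range."""
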