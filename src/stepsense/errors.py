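"""Exception hierarchy shared across the pipeline."""


class StepSenseError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StepSenseError, ValueError):
    """A model or design parameter violates its constraints."""


class InsufficientDataError(StepSenseError, ValueError):
    """Too few observations to carry out the requested computation."""


class DegenerateDesignError(StepSenseError, ValueError):
    """The design matrix is singular (e.g. zero variance in the regressor)."""


class NonInvertibleError(StepSenseError, ValueError):
    """A summary statistic cannot be mapped back to model parameters."""


class SchemaError(StepSenseError, ValueError):
    """A table or file does not match the expected column schema."""


class StateError(StepSenseError, ValueError):
    """A kinematic state is invalid for the requested geometry operation."""


class GenerationError(StepSenseError, RuntimeError):
    """Synthetic-data generation failed to satisfy its constraints."""


class FitError(StepSenseError, RuntimeError):
    """A statistical model could not be fitted to the supplied data."""
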