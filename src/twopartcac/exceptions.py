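"""Exception hierarchy for two-part CAC modelling."""


class TwoPartError(Exception):
    """Base class for all package-specific errors."""


class CohortValidationError(TwoPartError, ValueError):
    """A cohort table violates the schema (missing columns, negative CAC, NaNs...)."""


class DesignError(TwoPartError, ValueError):
    """A model specification cannot be realised on the given data."""


class DegenerateModelError(TwoPartError, ValueError):
    """The data cannot identify the requested model (e.g. no zero CAC values,
    complete separation in the logistic part, or an unidentified scale
    parameter when all covariate effects vanish)."""


class ConvergenceError(TwoPartError, RuntimeError):
    """The optimizer failed to reach a stationary point after the restart schedule."""
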