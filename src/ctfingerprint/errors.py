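"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented invariant (shapes, ids, ranges, weights)."""


class ParseError(ValidationError):
    """A delimited table contains a payload cell that is not a number."""


class UndefinedCovError(ValueError):
    """Coefficient of variance requested for data with zero mean."""


class AICcUndefinedError(ValueError):
    """Small-sample AIC correction undefined: n <= K + 1 for this model."""


class OptimizationError(RuntimeError):
    """No grid point could be scored during model selection."""
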