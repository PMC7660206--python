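"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid argument values or shapes."""


class ConfigurationError(ValueError):
    """Inconsistent parameter or configuration values."""


class UndefinedValueError(ValueError):
    """A quantity is mathematically undefined for the given inputs
    (zero denominator, negative discriminant, zero mean, ...)."""


class DegenerateFitError(ValueError):
    """A regression cannot be fitted (constant predictor or response)."""


class NumericalError(RuntimeError):
    """A linear-algebra step failed (singular or ill-conditioned matrix)."""
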