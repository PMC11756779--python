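"""Exception hierarchy shared across the package."""


class SynthArmError(Exception):
    """Base class for all package errors."""


class SchemaError(SynthArmError, ValueError):
    """A feature schema is internally inconsistent."""


class DataValidationError(SynthArmError, ValueError):
    """A value table violates its schema (names row/column where possible)."""


class ArgumentError(SynthArmError, ValueError):
    """An operation received an out-of-contract argument."""


class ConvergenceError(SynthArmError, RuntimeError):
    """A model fit did not converge; never reported as a silent number."""


class UndefinedMedianError(SynthArmError, RuntimeError):
    """A Kaplan-Meier curve never crosses 0.5, so its median is undefined."""
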