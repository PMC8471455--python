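"""Exception hierarchy shared across the package."""


class NeuroPBPKError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NeuroPBPKError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(NeuroPBPKError, ValueError):
    """A tabular input is missing columns or contains out-of-range values."""


class UndefinedResultError(NeuroPBPKError, ArithmeticError):
    """The requested quantity is mathematically undefined for this input."""


class SolverError(NeuroPBPKError, RuntimeError):
    """Numerical integration failed; carries the solver diagnostics."""


class ConfigurationError(NeuroPBPKError, ValueError):
    """A study configuration is inconsistent or incomplete."""
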