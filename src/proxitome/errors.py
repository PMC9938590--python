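"""Structured exception types used across the package."""


class ProxitomeError(Exception):
    """Base class for all package errors."""


class ValidationError(ProxitomeError):
    """Raised when an input file or in-memory container violates its contract.

    The message always names the offending row, column, sample or interval so
    that problems in large tables can be located without a debugger.
    """


class ConfigurationError(ProxitomeError):
    """Raised when a parameter set (simulation, imputation, pipeline YAML)
    fails its invariants before any computation starts."""
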