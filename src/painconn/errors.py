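"""Exception hierarchy shared across the pipeline."""


class PainConnError(Exception):
    """Base class for all painconn errors."""


class FormatError(PainConnError, ValueError):
    """A file could not be parsed as the expected delimited format."""


class ValidationError(PainConnError, ValueError):
    """Parsed data violates a structural or numerical invariant."""


class ConfigurationError(PainConnError, ValueError):
    """A pipeline configuration is missing or has an inconsistent key."""


class SimulationSpecError(PainConnError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class UndefinedCorrelationError(ValidationError):
    """Correlation requested on a constant (zero-variance) signal."""
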