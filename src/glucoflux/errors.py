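"""Exception hierarchy shared across the package."""


class GlucofluxError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GlucofluxError):
    """Invalid configuration value or malformed config file."""


class SchemaError(GlucofluxError):
    """Malformed network/prior/gene-set file; message names the record."""


class ValidationError(GlucofluxError):
    """Structural validation of a network or input table failed."""


class InsufficientDataError(GlucofluxError):
    """Too few samples/groups/genes for the requested statistic."""


class DomainError(GlucofluxError):
    """Numeric argument outside its mathematical domain."""


class InfeasibleError(GlucofluxError):
    """Optimization constraints cannot be satisfied."""


class SolverError(GlucofluxError):
    """Numerical solver failed to converge."""
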