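"""Exception hierarchy shared across the pipeline stages."""


class EcofluxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EcofluxError):
    """An input table is missing a required column or has the wrong layout."""


class IntegrityError(EcofluxError):
    """Row-level data violates the community data contract."""


class ParameterError(EcofluxError, ValueError):
    """A model parameter is outside its admissible range."""


class ConfigError(EcofluxError):
    """A configuration entry (coefficients, efficiencies, paths) cannot be resolved."""


class ReconstructionError(EcofluxError):
    """A food web cannot be assembled from the given traits."""


class EnergeticsError(EcofluxError):
    """The steady-state flux system is infeasible or singular."""
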