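"""Exception hierarchy shared across the pipeline stages."""


class ThermovarError(Exception):
    """Base class for all package errors."""


class ConfigError(ThermovarError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(ThermovarError):
    """Input table is missing a required column or has a wrong dtype."""


class EmptySeriesError(ThermovarError):
    """An operation that requires a non-empty series received an empty one."""


class InsufficientDataError(ThermovarError):
    """Not enough observations to compute the requested quantity."""


class UndefinedMetricError(ThermovarError):
    """The metric is mathematically undefined on this input (e.g. zero mean
    for CV, non-positive values for PV/D)."""


class ValidationError(ThermovarError):
    """Structural inconsistency in otherwise well-formed inputs
    (e.g. overlapping sleep windows, mismatched lag grids)."""


class NotApplicableError(ThermovarError):
    """Operation does not apply to this subject (e.g. phase alignment of an
    acyclic participant)."""
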