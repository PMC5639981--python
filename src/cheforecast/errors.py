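"""Exception hierarchy for the cheforecast pipeline.

All errors derive from :class:`CheForecastError` so callers can catch the
package's failures with a single except clause; schema/validation errors also
derive from :class:`ValueError` for ergonomic use in scripts.
"""


class CheForecastError(Exception):
    """Base class for all cheforecast errors."""


class SchemaError(CheForecastError, ValueError):
    """A tabular input is missing required columns or has the wrong layout."""


class ValidationError(CheForecastError, ValueError):
    """Input values violate a domain invariant (duplicates, orderings, ranges)."""


class DomainError(CheForecastError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class FittingError(CheForecastError, RuntimeError):
    """The mixed model could not be fitted (too few countries, non-convergence)."""


class ConfigError(CheForecastError, ValueError):
    """A run or generator configuration is inconsistent."""
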