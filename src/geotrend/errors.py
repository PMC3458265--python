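"""Exception hierarchy for geotrend."""


class GeotrendError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GeotrendError):
    """A mandatory column is missing or a header cannot be resolved."""


class TableParseError(GeotrendError):
    """A cell could not be parsed; carries row/column context in the message."""


class TableValidationError(GeotrendError):
    """A table violates a structural invariant (e.g. richness hierarchy)."""


class DegenerateInputError(GeotrendError):
    """An input is constant or otherwise leaves a statistic undefined."""


class CollinearityError(GeotrendError):
    """A design matrix is rank deficient / a predictor is exactly collinear."""


class ConfigError(GeotrendError):
    """An invalid configuration value."""
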