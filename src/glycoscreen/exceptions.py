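"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Raised when a configuration object or parameter is invalid."""


class InputDataError(ValueError):
    """Raised when input tables or sequences violate their contract."""


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. single-class ROC)."""
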