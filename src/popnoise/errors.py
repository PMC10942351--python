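"""Exception hierarchy for popnoise."""


class PopnoiseError(Exception):
    """Base class for all popnoise errors."""


class ConfigurationError(PopnoiseError, ValueError):
    """Invalid configuration or parameter value."""


class SchemaError(PopnoiseError):
    """A file is missing a required dataset, column or attribute."""


class AnalysisError(PopnoiseError, RuntimeError):
    """An analysis step received degenerate or insufficient data."""
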