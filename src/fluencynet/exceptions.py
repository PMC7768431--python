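"""Exception hierarchy for fluencynet."""


class FluencyNetError(Exception):
    """Base class for all fluencynet errors."""


class ConfigurationError(FluencyNetError):
    """Malformed input schema or run configuration (e.g. a missing column)."""


class ValidationError(FluencyNetError):
    """Input data violates a structural contract (e.g. duplicate response order)."""


class EmptyMatrixError(FluencyNetError):
    """Every response was eliminated during preprocessing."""


class EquatingError(FluencyNetError):
    """Cross-group response equating left too few shared words to build a network."""


class ParameterError(FluencyNetError):
    """Generator or model parameters are unusable (e.g. graph cannot be connected)."""
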