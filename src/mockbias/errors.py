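"""Exception types shared across the package."""


class MockbiasError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MockbiasError):
    """A table or file does not conform to the expected schema."""


class DesignError(MockbiasError):
    """Invalid or infeasible mixture-design request."""


class SimulationError(MockbiasError):
    """The generative model produced an invalid state (e.g. negative weights)."""


class MatchingError(MockbiasError):
    """Samples could not be matched to design rows or across experiments."""


class ConfigError(MockbiasError):
    """Invalid run configuration."""


class ModelError(MockbiasError):
    """Model fitting failed (rank deficiency, too few observations, ...)."""
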