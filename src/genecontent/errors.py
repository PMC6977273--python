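"""Exception hierarchy shared across the package."""


class GeneContentError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GeneContentError, ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


class ValidationError(GeneContentError, ValueError):
    """Raised when parsed input violates a semantic invariant."""


class DegenerateRegressionError(ValidationError):
    """Raised when a regression has no usable spread in its predictor."""


class SimulationError(GeneContentError, RuntimeError):
    """Raised when a simulator cannot satisfy its constraints."""
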