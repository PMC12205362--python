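"""Package-level exception types."""


class ScfretError(Exception):
    """Base class for scfret errors."""


class InvalidParameterError(ScfretError, ValueError):
    """A physically or numerically invalid parameter was supplied."""


class ConfigurationError(ScfretError, ValueError):
    """Inputs are inconsistent with the experiment configuration (e.g. schedule)."""


class FitFailureError(ScfretError, RuntimeError):
    """A model fit failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class DegenerateGeometryError(ScfretError, ValueError):
    """Too few or collinear control points for channel registration."""
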