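"""Exception hierarchy for the goredox pipeline."""


class GoredoxError(Exception):
    """Base class for all package-specific errors."""


class InvalidPixelError(GoredoxError):
    """A pixel channel value is outside the 8-bit range 0..255."""


class OutOfBoundsError(GoredoxError):
    """A pixel box or region of interest crosses an image boundary."""


class InvalidPointError(GoredoxError):
    """A sampling point failed validation (glare or bounds)."""


class InsufficientAreaError(GoredoxError):
    """Not enough glare-free area to place the requested number of boxes."""


class DegenerateVarianceError(GoredoxError):
    """A test statistic is undefined because sample variances are zero."""


class FitFailureError(GoredoxError):
    """A nonlinear fit did not converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(GoredoxError):
    """Run configuration is malformed (unknown keys, out-of-range values)."""
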