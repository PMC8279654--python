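"""Exception hierarchy shared across the pipeline."""


class SurfpropError(Exception):
    """Base class for all package errors."""


class InputError(SurfpropError, ValueError):
    """Invalid argument values (non-finite coordinates, bad selections, ...)."""


class ConfigurationError(SurfpropError):
    """A parameter set that is internally inconsistent or numerically unsafe."""


class ParseError(SurfpropError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConvergenceError(SurfpropError):
    """Iteration did not reach tolerance; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class WindowOverlapError(SurfpropError):
    """An umbrella window contributes no samples to the analysis range."""


class ReferencingError(SurfpropError):
    """Reference coordinate falls in an undefined or out-of-range bin."""


class ProfileRangeError(SurfpropError):
    """Requested coordinate lies outside the defined profile range."""


class RegionSearchError(SurfpropError):
    """No defined bins inside the requested search region."""


class GeometryError(SurfpropError):
    """Geometric analysis failed (e.g. no interface crossing in a profile)."""
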