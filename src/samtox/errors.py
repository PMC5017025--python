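"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`SamtoxError`, so callers
can catch the package's failures without swallowing programming errors.
"""


class SamtoxError(Exception):
    """Base class for all samtox errors."""


class ParameterDomainError(SamtoxError, ValueError):
    """A model parameter is outside its mathematical domain (e.g. b <= 0)."""


class DegenerateCurveError(SamtoxError, ValueError):
    """The dose-response curve is degenerate (e.g. upper limit d = 0)."""


class DegenerateDataError(SamtoxError, ValueError):
    """The data carry no concentration effect; a curve cannot be fitted."""


class OutOfRangeError(SamtoxError, ValueError):
    """A requested effect level is unattainable on the given curve."""


class FitFailureError(SamtoxError, RuntimeError):
    """Curve fitting did not converge from any starting point.

    Carries the per-start diagnostics in ``.diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class EffectLevelUnreachableError(SamtoxError, ValueError):
    """The environmental stress alone exceeds the requested effect level,
    so the shifted lethal concentration LCx* is undefined."""


class CalibrationError(SamtoxError, ValueError):
    """Shape calibration is impossible (no study with env mortality > 0)."""


class InputError(SamtoxError, ValueError):
    """Invalid input data (empty sequence, too few points, ...)."""


class SchemaError(SamtoxError, ValueError):
    """A CSV file violates the documented schema; message names the row."""
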