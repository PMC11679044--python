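"""Exception hierarchy for strip-reader pipeline failures.

Every error raised by the package derives from :class:`StripSpecError`, so
callers (and the CLI) can distinguish data problems from programming bugs.
"""


class StripSpecError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(StripSpecError):
    """A spectrum file contained a malformed row; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class InsufficientDataError(StripSpecError):
    """Fewer observations than the operation's statistical minimum."""


class SpectrumValidationError(StripSpecError):
    """A spectrum or derived object violates a structural invariant."""


class GridMismatchError(StripSpecError):
    """Wavelength grids of spectra that must align do not match exactly."""

    def __init__(self, message: str, offending_wavelengths=None):
        super().__init__(message)
        self.offending_wavelengths = offending_wavelengths


class SchemaVersionError(StripSpecError):
    """A persisted file declares a schema version this code cannot read."""


class ParameterError(StripSpecError):
    """An operation was called with out-of-contract parameters."""


class EmptyProfileError(StripSpecError):
    """All points of an absorbance profile were invalid."""


class EmptyBandError(StripSpecError):
    """No valid absorbance point falls inside the peak-search band."""


class InvalidStripError(StripSpecError):
    """The control line failed (non-positive C-line signal); strip is void."""


class FitFailureError(StripSpecError):
    """Calibration fit did not converge; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedStatisticError(StripSpecError):
    """A statistic (CV, ICC, correlation) is undefined for the given data."""
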