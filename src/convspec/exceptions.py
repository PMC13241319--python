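"""Exception hierarchy for convspec.

All package-specific failures derive from :class:`ConvSpecError` so callers
can distinguish domain errors from programming errors.  The CLI maps these
onto exit codes (config -> 2, numerical -> 3, file format/IO -> 4).
"""


class ConvSpecError(Exception):
    """Base class for all convspec errors."""


class DegenerateStageError(ConvSpecError, ValueError):
    """Splitting ratio rho is 0 or 1: the stage has no modulation depth."""


class WindowMismatchError(ConvSpecError, ValueError):
    """Grid span does not equal the cascade's composite FSR.

    The circular-convolution identity only holds when one grid window is
    exactly one composite free spectral range.
    """


class IncommensurableFSRError(ConvSpecError, ValueError):
    """Stage FSRs have no rational relation within tolerance; no finite
    composite FSR exists."""


class MisalignmentError(ConvSpecError, ValueError):
    """Phase schedule is not aligned to the wavenumber grid (n_steps != N),
    so grid-exact circular shifting is impossible."""


class DispersionError(ConvSpecError, ValueError):
    """Dispersion model invalid over the grid (non-positive group index or
    non-monotone phase map)."""


class UnrecoverableError(ConvSpecError, ArithmeticError):
    """Every DFT bin was suppressed during regularized division; nothing of
    the incident spectrum can be recovered."""


class AmbiguousRegistrationError(ConvSpecError, ArithmeticError):
    """Circular cross-correlation against the calibration has no unique
    maximum; the shift origin cannot be registered."""


class ConfigError(ConvSpecError, ValueError):
    """Invalid run configuration (missing file, out-of-range parameter)."""


class FormatError(ConvSpecError, ValueError):
    """Malformed on-disk data."""


class MalformedFileError(FormatError):
    """File cannot be parsed as the expected CSV/JSON layout."""


class NonUniformGridError(FormatError):
    """Wavenumber column is not strictly increasing and uniformly spaced."""


class NegativeIntensityError(FormatError):
    """Spectrum file carries negative intensities."""
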