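"""Exception types shared across the toolkit."""


class HsicalError(Exception):
    """Base class for all toolkit errors."""


class CubeFormatError(HsicalError, ValueError):
    """A cube file header is malformed; the message names the offending key."""


class CubeSizeError(HsicalError, ValueError):
    """Header-declared extents disagree with the binary payload."""


class WavelengthRangeError(HsicalError, ValueError):
    """A requested wavelength lies outside the calibrated/covered range."""


class InsufficientDataError(HsicalError, ValueError):
    """Not enough lines/peaks/periods/time points for the requested estimate."""


class ConditioningError(HsicalError, ValueError):
    """A least-squares design matrix is (numerically) rank deficient."""

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class DegenerateInputError(HsicalError, ValueError):
    """Input is valid in form but carries no usable signal (e.g. no absorption)."""
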