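"""Exception hierarchy shared across the package."""


class CardiogateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CardiogateError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class UnsupportedFormatError(FormatError):
    """The file is syntactically valid but uses an unsupported variant."""


class ValidationError(CardiogateError, ValueError):
    """A domain object violates one of its invariants."""


class InsufficientDataError(CardiogateError, ValueError):
    """Too few observations to compute the requested statistic."""


class CalibrationError(CardiogateError, ValueError):
    """A calibration input is unusable (e.g. silent reference tone)."""


class DegenerateSignalError(CardiogateError, ValueError):
    """A signal carries no usable structure (e.g. constant trace)."""
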