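"""Exception hierarchy shared across the package."""


class OrsmokeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OrsmokeError):
    """A file does not conform to its documented layout."""


class ValidationError(OrsmokeError):
    """Parsed content violates a domain invariant."""


class ParameterError(OrsmokeError, ValueError):
    """A function argument is outside its admissible range."""


class ProcessingError(OrsmokeError):
    """A signal-processing step cannot be applied to the given series."""


class CalibrationError(ProcessingError):
    """A channel's calibration segment cannot yield a sensitivity factor."""


class GroupingError(OrsmokeError):
    """A statistical grouping is missing a required factor level."""


class DecompositionError(OrsmokeError):
    """The least-squares design matrix is rank deficient."""
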