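"""Exception hierarchy used across the package."""


class NapscapeError(Exception):
    """Base class for all package errors."""


class FormatError(NapscapeError):
    """A file could not be parsed in its declared format."""


class ValidationError(NapscapeError):
    """An in-memory object violates one of its invariants."""


class ParameterError(NapscapeError):
    """A parameter value is outside its admissible range."""


class AlignmentError(NapscapeError):
    """Two inputs (e.g. recording and hypnogram) do not cover the same time span."""


class InsufficientDataError(NapscapeError):
    """Not enough eligible data to compute the requested quantity."""


class ExclusionError(NapscapeError):
    """The recording must be excluded from analysis (e.g. bad mastoid channels)."""

    def __init__(self, message: str, reason_code: str = "excluded"):
        super().__init__(message)
        self.reason_code = reason_code
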