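"""Exception types shared across the package."""


class ExoassistError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ExoassistError, ValueError):
    """A parameter violates a documented invariant."""


class InputError(ExoassistError, ValueError):
    """An input signal violates a precondition (e.g. negative load)."""


class FormatError(ExoassistError, ValueError):
    """A file does not conform to the expected columnar text format."""


class DegeneratePortraitError(ExoassistError, ValueError):
    """The hip-angle phase portrait collapsed (zero peak-to-peak amplitude)."""


class DataLengthError(ExoassistError, ValueError):
    """A series is too short for the requested operation."""


class InsufficientDataError(ExoassistError, ValueError):
    """Not enough gait events present to compute the requested quantity."""
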