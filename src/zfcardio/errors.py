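"""Exception hierarchy for zfcardio.

All package-raised errors derive from :class:`ZfcardioError` so callers can
catch everything from one base, while the subclasses distinguish bad inputs
from bad configuration and from per-frame analysis failures.
"""


class ZfcardioError(Exception):
    """Base class for all errors raised by zfcardio."""


class InputError(ZfcardioError):
    """A required input (file, path) is missing or unreadable."""


class FormatError(ZfcardioError):
    """An input exists but violates the expected format or invariants."""


class ConfigError(ZfcardioError):
    """A parameter or option value is not recognised or inconsistent."""


class ParameterError(ZfcardioError):
    """A numeric parameter is outside its valid domain."""


class SegmentationError(ZfcardioError):
    """The lumen could not be delineated in a frame (or too many frames)."""


class AnalysisError(ZfcardioError):
    """A downstream computation is undefined for the given data."""
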