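"""Exception hierarchy."""


class CopromitoError(Exception):
    """Base class for all package errors."""


class ParameterError(CopromitoError, ValueError):
    """A parameter is outside its documented domain."""


class ParseError(CopromitoError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class ConfigError(CopromitoError, ValueError):
    """Invalid or inconsistent pipeline configuration."""


class BandExceededError(CopromitoError, RuntimeError):
    """Banded global alignment cannot accommodate the inputs; enlarge the band."""


class InsufficientOverlapError(CopromitoError, ValueError):
    """Two samples share too few called sites for a distance to be meaningful."""
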