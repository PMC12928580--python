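"""Exception types shared across the package."""


class CCCLinkError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(CCCLinkError, ValueError):
    """A file could not be parsed or its dimensions are inconsistent."""


class ValidationError(CCCLinkError, ValueError):
    """An in-memory object violates a structural invariant."""


class ParameterError(CCCLinkError, ValueError):
    """A user-supplied parameter is outside its admissible range."""
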