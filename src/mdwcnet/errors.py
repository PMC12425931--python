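"""Exception types shared across the package."""


class MDWCNetError(Exception):
    """Base class for package errors."""


class ConfigurationError(MDWCNetError):
    """Invalid architecture / training / phantom configuration."""


class InvalidInputError(MDWCNetError):
    """Inputs violate a documented precondition (shape, range, labels)."""


class DegenerateInputError(MDWCNetError):
    """Statistically degenerate input (e.g. zero-variance paired differences)."""
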