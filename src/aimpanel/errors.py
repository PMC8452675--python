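"""Exception hierarchy shared across the pipeline stages."""


class AimpanelError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AimpanelError, ValueError):
    """Invalid parameter or malformed in-memory data."""


class FormatError(AimpanelError, ValueError):
    """Unreadable or structurally invalid input file."""


class ConfigurationError(AimpanelError):
    """Missing or contradictory configuration (no silent defaults)."""


class DataIntegrityError(AimpanelError):
    """Internally inconsistent data, e.g. leave-one-out subtraction below zero."""


class DegenerateModelError(AimpanelError):
    """A likelihood or moment is undefined for the supplied frequencies."""
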