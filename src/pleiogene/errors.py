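"""Exception hierarchy shared across the package."""


class PleiogeneError(Exception):
    """Base class for all package errors."""


class FormatError(PleiogeneError):
    """A file does not match the expected layout (missing columns, bad header)."""


class ValidationError(PleiogeneError):
    """Parsed content violates a domain invariant (duplicates, range violations)."""


class ConfigError(PleiogeneError):
    """Invalid or inconsistent run configuration."""


class NotPositiveSemidefiniteError(PleiogeneError):
    """An LD matrix is not PSD; condition it with ``condition_psd`` first."""
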