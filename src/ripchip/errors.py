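"""Exception hierarchy shared across the package."""


class RipChipError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RipChipError):
    """A configuration value is outside its documented domain."""


class FormatError(RipChipError):
    """An input file does not match the expected layout."""


class DesignError(RipChipError):
    """Sample metadata is inconsistent with the signal matrix or the
    dye-replicate pairing the analysis requires."""


class UsageError(RipChipError):
    """An operation was invoked with arguments that make it undefined
    (e.g. comparing a construct against itself)."""
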