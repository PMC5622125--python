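"""Exception hierarchy.

All package-raised errors derive from :class:`MsapkitError` so callers can
catch everything with one except clause; subclasses distinguish bad user
configuration from malformed input files and mathematically undefined
results.
"""


class MsapkitError(Exception):
    """Base class for all msapkit errors."""


class ConfigurationError(MsapkitError):
    """A configuration value is invalid; the message names the field."""


class FormatError(MsapkitError):
    """An input file does not conform to the declared dialect."""


class UndefinedValueError(MsapkitError):
    """A requested quantity is mathematically undefined for this input."""
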