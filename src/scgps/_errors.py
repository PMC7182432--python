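"""Exception hierarchy.

All user-facing failures raise a subclass of :class:`ScgpsError` so callers
(and the CLI) can distinguish bad inputs from genuine bugs.
"""


class ScgpsError(Exception):
    """Base class for all scgps errors."""


class FormatError(ScgpsError):
    """A file does not conform to its declared format."""


class DataError(ScgpsError):
    """Inputs are well-formed but violate a data contract."""


class ConfigError(ScgpsError):
    """A configuration object is invalid."""
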