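"""Exception hierarchy shared across the package."""


class KnotpopError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KnotpopError):
    """A file or cell does not conform to the expected dialect."""


class IdentityError(KnotpopError):
    """Sample identity violated (duplicate or unknown sample ids)."""


class AlignmentError(KnotpopError):
    """Evidence layers cannot be aligned on a shared sample set."""


class ConfigError(KnotpopError):
    """Invalid configuration or simulation parameters."""


class StructureError(KnotpopError):
    """Population structure requirements not met (e.g. a single population)."""
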