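"""Typed exceptions shared across the package."""


class TriHingeError(Exception):
    """Base class for all package errors."""


class FormatError(TriHingeError, ValueError):
    """A file does not parse under the declared on-disk format."""


class DimensionError(TriHingeError, ValueError):
    """Array shapes or lengths are inconsistent."""


class ConfigError(TriHingeError, ValueError):
    """A configuration value is invalid or incompatible."""


class DependencyError(TriHingeError, RuntimeError):
    """A pipeline stage requires an artifact that does not exist."""
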