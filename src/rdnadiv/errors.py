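"""Exception hierarchy shared across the package."""


class RdnadivError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RdnadivError, ValueError):
    """A file does not conform to the expected format."""


class AnnotationError(RdnadivError, ValueError):
    """Element or structure annotation violates an invariant."""


class CoordinateError(RdnadivError, ValueError):
    """A position falls outside the valid coordinate domain."""


class ConfigError(RdnadivError, ValueError):
    """An invalid configuration value."""


class DataError(RdnadivError, ValueError):
    """Input data violates a precondition (negative counts, inconsistent copies...)."""
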