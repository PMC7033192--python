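"""Exception hierarchy shared across the package."""


class GraphDMDError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GraphDMDError, ValueError):
    """Input data violates a structural precondition (shape, roles, finiteness)."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but carries no signal (e.g. an all-zero tensor)."""


class SegmentInvalidError(GraphDMDError, RuntimeError):
    """A trajectory segment has no valid sliding window and must be excluded."""


class ConfigError(GraphDMDError, ValueError):
    """Unknown option, mask name, or malformed configuration value."""
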