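"""Exception hierarchy for the package."""


class MCPainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MCPainError):
    """Malformed input table or image (bad columns, duplicate ids, ...)."""


class InvalidParameterError(MCPainError, ValueError):
    """A parameter violates its contract (non-positive SD, bad schedule, ...)."""


class DegenerateSampleError(MCPainError, ValueError):
    """A sample vector is too small or constant for density estimation."""


class GridMismatchError(MCPainError, ValueError):
    """Two density estimates do not share an evaluation grid."""
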