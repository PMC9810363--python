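"""Exception hierarchy.

All edgeflow errors derive from :class:`EdgeflowError` so callers can catch
the whole family; each also derives from ``ValueError`` because every one of
them signals an invalid input rather than an internal failure.
"""


class EdgeflowError(ValueError):
    """Base class for all edgeflow errors."""


class ConfigurationError(EdgeflowError):
    """A simulation or pipeline configuration is internally inconsistent."""


class FormatError(EdgeflowError):
    """A file could not be parsed as a multichannel recording."""


class ValidationError(EdgeflowError):
    """An operation's preconditions on its inputs are violated."""


class DegenerateSignalError(EdgeflowError):
    """A signal carries no usable variation (constant input, zero phase variance)."""


class NoOscillationError(EdgeflowError):
    """A phase series never completes an oscillation, so no analysis lag exists."""
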