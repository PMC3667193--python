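"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`MicrocensusError`, so callers (and the batch runner, which must
isolate per-box failures) can catch one type.
"""


class MicrocensusError(Exception):
    """Base class for all errors raised by microcensus."""


class ValidationError(MicrocensusError, ValueError):
    """An input violates a documented precondition or invariant."""


class StackIOError(MicrocensusError, OSError):
    """An image file could not be read or written; the message names the path."""


class DegenerateImageError(MicrocensusError):
    """An image has no usable contrast (e.g. constant input to Otsu)."""


class CalibrationError(MicrocensusError):
    """The physical-scale reference square could not be found or is implausible."""


class RoiDetectionError(MicrocensusError):
    """Automatic arena detection failed; a manual ROI should be supplied."""
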