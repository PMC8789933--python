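"""Exception hierarchy for the heart-sound pipeline."""


class HeartSoundError(Exception):
    """Base class for all errors raised by this package."""


class InputError(HeartSoundError):
    """Unreadable, corrupt, or empty input recording."""


class ParameterError(HeartSoundError, ValueError):
    """A parameter is outside its admissible range."""


class DegenerateInputError(HeartSoundError, ValueError):
    """Input is structurally valid but degenerate (all-zero trace, too short)."""


class SegmentationError(HeartSoundError):
    """The cycle segmenter could not locate enough boundary events.

    Raised when the STMHT curve has too few sign changes to pair
    complete cardiac cycles; such recordings cannot be diagnosed.
    """


class DataError(HeartSoundError, ValueError):
    """A dataset violates the preconditions of a fit (size, finiteness, labels)."""


class PackagingError(HeartSoundError):
    """A bundled resource is missing or corrupt."""
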