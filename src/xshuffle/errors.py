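"""Exception hierarchy for xshuffle.

All library errors derive from :class:`XShuffleError` so callers can catch one
type at the CLI boundary.
"""


class XShuffleError(Exception):
    """Base class for all xshuffle errors."""


class DimensionError(XShuffleError):
    """Image or vector dimensions are invalid or inconsistent."""


class DivisibilityError(XShuffleError):
    """Image side not divisible by the requested block size."""


class LayoutError(XShuffleError):
    """Block list inconsistent with the grid layout it claims to fill."""


class SegmentationError(XShuffleError):
    """Segmentation map inconsistent with the image it is applied to."""


class TransferError(XShuffleError):
    """Region transfer asked to fill a nonempty target from an empty source."""


class ParameterError(XShuffleError):
    """A numeric parameter is outside its documented range."""


class SpecError(XShuffleError):
    """A transform spec is malformed or names an unknown family."""


class SamplingError(XShuffleError):
    """Not enough source images to build the requested stimulus set."""


class PairingError(XShuffleError):
    """Paired samples differ in length or labels."""


class DegenerateVarianceError(XShuffleError):
    """A statistic is undefined because a sample has zero variance."""


class FilteringError(XShuffleError):
    """Participant filtering excluded every observer."""
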