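"""Exception types raised by the leaftooth pipeline."""


class LeafToothError(Exception):
    """Base class for all leaftooth errors."""


class InvalidInputError(LeafToothError):
    """Input image or array does not satisfy the operation's contract."""


class DegenerateSegmentationError(LeafToothError):
    """Segmentation is impossible (e.g. constant-intensity image)."""


class NoLeafError(LeafToothError):
    """No foreground component found in the mask."""


class TooShortCurveError(LeafToothError):
    """Contour is shorter than the Gaussian kernel support."""


class InvalidSpecError(LeafToothError):
    """Synthetic leaf specification is geometrically infeasible."""
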