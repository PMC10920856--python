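"""Exception hierarchy shared by all pipeline stages.

Every anticipated failure mode raises a subclass of :class:`CMEError`, so a
time-lapse driver can catch one type, record the frame as failed, and move on.
"""


class CMEError(Exception):
    """Base class for all errors raised by the cme package."""


class NoThresholdError(CMEError):
    """Constant-intensity image: Otsu's criterion has no threshold."""


class DegenerateSegmentationError(CMEError):
    """Thresholding produced an all-foreground or all-background mask."""


class NoObjectError(CMEError):
    """Mask contains no foreground pixels."""


class ObjectTooSmallError(CMEError):
    """Largest connected component is below the minimum area."""


class DegenerateObjectError(CMEError):
    """Object is too thin (no 2x2 foreground block) to carry a boundary."""


class ZeroRadiusError(CMEError):
    """A boundary point coincides with the centroid."""


class LagTooLargeError(CMEError):
    """Boundary has fewer than ``2 * dN`` points."""


class InsufficientBoundaryError(CMEError):
    """Fewer than two points: no displacement can be formed."""


class NoDisplacementsError(CMEError):
    """Empty or too-short displacement sample for a histogram."""


class DegenerateEllipseError(CMEError):
    """Moment ellipse has a vanishing minor axis (e.g. a 1-px line)."""


class ConstantSeriesError(CMEError):
    """Zero-variance series where a normalized statistic is undefined."""
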