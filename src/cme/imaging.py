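"""Segmentation and boundary extraction for single-object micrographs.

This module turns one grayscale frame (a nucleus, a single cell, or a whole
spheroid on a dark background) into a clean binary mask of the single largest
object, and extracts the object's ordered boundary and area centroid.  The
steps mirror the classical fluorescence-microscopy recipe:

1. optional Gaussian smoothing to suppress shot noise,
2. automatic global thresholding by Otsu's criterion,
3. hole filling and retention of the largest 8-connected component,
4. Moore-neighbor boundary tracing on the pixel lattice.

Coordinate convention
---------------------
Internally ``x = column`` and ``y = row``, with ``y`` increasing downward as
in every raster image format.  Angles reported downstream use the
mathematical convention (counterclockwise positive), obtained by negating
``y`` when converting to polar coordinates; boundaries returned here are
ordered counterclockwise in that mathematical frame.

Subpixel contouring is deliberately not used: displacements between
consecutive boundary points are meant to live on the pixel lattice, and the
lag subsampling applied downstream is what removes pixel-level "burrs".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .exceptions import (
    DegenerateObjectError,
    DegenerateSegmentationError,
    NoObjectError,
    NoThresholdError,
    ObjectTooSmallError,
)

logger = logging.getLogger("cme")

#: 3x3 structuring element: 8-connectivity for components and tracing.
_STRUCT8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrayFrame:
    """A single grayscale frame.

    Parameters
    ----------
    pixels
        2-D array of intensities, any integer or float scale.
    pixel_size
        Physical size of one pixel in micrometres (default 1.0, i.e. work
        in pixel units).
    timestamp
        Acquisition time in minutes, if known.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    timestamp: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
            raise ValueError("frame must be a 2-D grid of at least 3x3 pixels")
        if not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("frame contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", arr)


@dataclass(frozen=True)
class BinaryMask:
    """A two-level mask; after :func:`clean_mask` it holds exactly one
    hole-free connected component."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", arr.astype(bool))

    @property
    def area(self) -> float:
        """Foreground area in physical units (``pixel_size**2`` per pixel)."""
        return float(self.pixels.sum()) * self.pixel_size**2


@dataclass(frozen=True)
class Boundary:
    """Ordered closed boundary of a single object.

    ``points`` is an ``(n, 2)`` array of ``(x, y)`` coordinates in physical
    units (image convention, ``y`` down), traced so that traversal is
    counterclockwise in the mathematical frame.  ``centroid`` is the area
    centroid of the filled mask (mean of foreground pixel coordinates).
    """

    points: np.ndarray
    centroid: tuple[float, float]
    area: float
    closed: bool = True
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("boundary needs an (n>=3, 2) point array")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def binarize(
    frame: GrayFrame,
    smoothing_radius: float = 1.0,
    invert: bool = False,
) -> BinaryMask:
    """Threshold a grayscale frame with Otsu's criterion.

    A single Gaussian pass (sigma ``smoothing_radius`` pixels, 0 disables)
    reduces noise before the histogram is thresholded.  By default the
    brighter side becomes foreground (fluorescence polarity); ``invert``
    selects the darker side for brightfield images.

    Raises
    ------
    NoThresholdError
        If the (smoothed) image is constant.
    DegenerateSegmentationError
        If thresholding yields an all-foreground or all-background mask.
    """
    from skimage.filters import threshold_otsu

    arr = np.asarray(frame.pixels, dtype=float)
    if np.ptp(arr) == 0:
        raise NoThresholdError("no threshold: constant image")
    if smoothing_radius > 0:
        arr = ndimage.gaussian_filter(arr, sigma=smoothing_radius)
        if np.ptp(arr) == 0:
            raise NoThresholdError("no threshold: constant image after smoothing")
    thresh = threshold_otsu(arr)
    fg = arr < thresh if invert else arr > thresh
    if fg.all() or not fg.any():
        raise DegenerateSegmentationError(
            "degenerate segmentation: threshold separated nothing"
        )
    return BinaryMask(fg, pixel_size=frame.pixel_size)


def clean_mask(mask: BinaryMask, min_area: float = 50.0) -> BinaryMask:
    """Fill holes and keep only the largest 8-connected component.

    ``min_area`` is in pixels²; the cleaned component must reach it.

    Raises
    ------
    NoObjectError
        If the mask is empty.
    ObjectTooSmallError
        If the largest component is below ``min_area``.
    """
    fg = mask.pixels
    if not fg.any():
        raise NoObjectError("no object: empty mask")
    filled = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(filled, structure=_STRUCT8)
    if n == 0:
        raise NoObjectError("no object: empty mask")
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] < min_area:
        raise ObjectTooSmallError(
            f"object too small: {counts[best - 1]} px² < min_area={min_area}"
        )
    return BinaryMask(labels == best, pixel_size=mask.pixel_size)


def extract_boundary(mask: BinaryMask) -> Boundary:
    """Trace the ordered boundary of a cleaned mask.

    Moore-neighbor tracing (Jacob's stopping criterion) yields a closed
    chain of boundary pixels in which consecutive points are 8-neighbors;
    the chain is then oriented counterclockwise in the mathematical frame.
    The centroid is the mean of all foreground pixel coordinates and the
    area is the foreground pixel count times ``pixel_size**2``.

    Raises
    ------
    NoObjectError
        If the mask is empty.
    DegenerateObjectError
        If the object is thinner than 2 px everywhere (no 2x2 block) or the
        traced chain has fewer than 8 points.
    """
    fg = mask.pixels
    if not fg.any():
        raise NoObjectError("no object: empty mask")
    # a component with no 2x2 foreground block is a line or a point
    blocks = fg[:-1, :-1] & fg[1:, :-1] & fg[:-1, 1:] & fg[1:, 1:]
    if not blocks.any():
        raise DegenerateObjectError("degenerate object: thinner than 2 px everywhere")

    chain = _moore_trace(fg)
    if chain.shape[0] < 8:
        raise DegenerateObjectError("degenerate object: boundary shorter than 8 px")

    ps = mask.pixel_size
    pts = np.column_stack([chain[:, 1], chain[:, 0]]).astype(float)  # (x=col, y=row)
    # counterclockwise in math frame: shoelace on (x, -y) must be positive
    x, y = pts[:, 0], -pts[:, 1]
    signed2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed2 < 0:
        pts = pts[::-1]
    rows, cols = np.nonzero(fg)
    centroid = (float(cols.mean()) * ps, float(rows.mean()) * ps)
    return Boundary(
        points=pts * ps,
        centroid=centroid,
        area=float(fg.sum()) * ps**2,
        closed=True,
        pixel_size=ps,
    )


# clockwise Moore neighborhood starting at W, in (row, col) offsets
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _moore_trace(fg: np.ndarray) -> np.ndarray:
    """Ordered boundary pixels of ``fg`` as an (n, 2) array of (row, col)."""
    pad = np.pad(fg, 1)
    rows, cols = np.nonzero(pad)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    b0 = (start[0], start[1] - 1)  # background by scan order
    chain = [start]
    cur, back = start, b0
    max_steps = 4 * int(pad.sum()) + 8
    for _ in range(max_steps):
        i = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            off = _MOORE[(i + k) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if pad[cand]:
                nxt = cand
                break
            back = cand
        if nxt is None:  # isolated pixel
            break
        if nxt == start and back == b0:  # Jacob's stopping criterion
            break
        chain.append(nxt)
        cur = nxt
    return np.asarray(chain, dtype=int) - 1  # undo padding


def segment_frame(
    frame: GrayFrame,
    smoothing_radius: float = 1.0,
    min_area: float = 50.0,
    invert: bool = False,
) -> BinaryMask:
    """Convenience: :func:`binarize` then :func:`clean_mask`."""
    return clean_mask(binarize(frame, smoothing_radius, invert), min_area)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    pixel_size: float = 1.0,
    frame_interval: float | None = None,
) -> list[GrayFrame]:
    """Read a time-lapse stack into a list of :class:`GrayFrame`.

    ``path`` may be a single- or multi-page TIFF, a single PNG, or a
    directory of per-frame TIFF/PNG files (lexicographic frame order).
    8/16-bit integer and float grayscale data are accepted; RGB(A) frames
    are reduced to luma.  ``frame_interval`` (minutes) sets timestamps
    ``0, dt, 2 dt, ...``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".tif", ".tiff", ".png"}
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG frames in {path}")
        planes = [_read_plane(f) for f in files]
    elif path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        planes = [_as_gray(p) for p in (data if data.ndim >= 3 else [data])]
    else:
        planes = [_read_plane(path)]
    frames = []
    for i, plane in enumerate(planes):
        t = None if frame_interval is None else i * frame_interval
        frames.append(GrayFrame(plane, pixel_size=pixel_size, timestamp=t))
    return frames


def _read_plane(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _as_gray(tifffile.imread(path))
    return _as_gray(iio.imread(path))


def _as_gray(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luma
        arr = arr[..., :3].astype(float) @ np.array([0.2126, 0.7152, 0.0722])
    if arr.ndim != 2:
        arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as a frame")
    return arr
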