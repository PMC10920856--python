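"""Complementary descriptors: moment-ellipse aspect ratio and the
radial-angular cross-correlation of boundary displacements."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .exceptions import ConstantSeriesError, DegenerateEllipseError, NoObjectError
from .imaging import BinaryMask
from .polar import DisplacementSeries


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a mask; ``aspect_ratio = major/minor``."""

    major_axis_length: float
    minor_axis_length: float
    orientation: float
    aspect_ratio: float


@dataclass(frozen=True)
class CrossCorrelation:
    """Normalized cross-correlation ``C(n)`` between radial and angular
    displacement components at integer lags ``n``."""

    lags: np.ndarray
    values: np.ndarray
    dr_mean: float
    dtheta_mean: float
    sigma_r2: float
    sigma_theta2: float


def ellipse_aspect_ratio(mask: BinaryMask) -> EllipseFit:
    """Fit the ellipse with the same second central moments as the region.

    Axis lengths follow the standard convention ``4 * sqrt(eigenvalue)`` of
    the covariance of foreground pixel coordinates (the full axes of the
    moment-equivalent ellipse), in the mask's physical units.

    Raises
    ------
    NoObjectError
        Empty mask.
    DegenerateEllipseError
        Vanishing minor axis (e.g. a 1-px-wide line).
    """
    fg = mask.pixels
    if not fg.any():
        raise NoObjectError("no object: empty mask")
    props = measure.regionprops(fg.astype(np.uint8))[0]
    major = props.axis_major_length * mask.pixel_size
    minor = props.axis_minor_length * mask.pixel_size
    if minor <= 1e-9:
        raise DegenerateEllipseError("degenerate ellipse: zero minor axis")
    return EllipseFit(
        major_axis_length=float(major),
        minor_axis_length=float(minor),
        orientation=float(props.orientation),
        aspect_ratio=float(major / minor),
    )


def cross_correlation(ds: DisplacementSeries, max_lag: int = 20) -> CrossCorrelation:
    """Normalized cross-correlation of the two displacement components.

    For each lag ``n`` in ``[-max_lag, max_lag]`` the deviation products
    ``(dr_j - mean_dr)(dtheta_{j+n} - mean_dtheta)`` are averaged over all
    overlapping ``j`` (no zero padding) and divided by the product of the
    full-series standard deviations, which are computed once.

    Raises
    ------
    ConstantSeriesError
        If either component has zero variance.
    ValueError
        If the series is too short for the requested lag window.
    """
    m = ds.m
    if m < max_lag + 2:
        raise ValueError(f"series too short: m={m} for max_lag={max_lag}")
    a = ds.dr - ds.dr.mean()
    b = ds.dtheta - ds.dtheta.mean()
    s_r2 = float(np.mean(a**2))
    s_t2 = float(np.mean(b**2))
    if s_r2 == 0 or s_t2 == 0:
        raise ConstantSeriesError("constant series: zero variance component")
    denom = np.sqrt(s_r2) * np.sqrt(s_t2)
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(lags.size)
    for i, n in enumerate(lags):
        if n >= 0:
            prod = a[: m - n] * b[n:]
        else:
            prod = a[-n:] * b[: m + n]
        vals[i] = prod.mean() / denom
    return CrossCorrelation(
        lags=lags,
        values=vals,
        dr_mean=float(ds.dr.mean()),
        dtheta_mean=float(ds.dtheta.mean()),
        sigma_r2=s_r2,
        sigma_theta2=s_t2,
    )
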