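"""Polar parameterization of a boundary and lag-subsampled displacements.

The traced boundary is mapped into polar coordinates ``(r_i, theta_i)``
about the object centroid, subsampled with an integer lag ``dN`` to discard
pixel-level "burrs", and differenced into consecutive radial and angular
boundary displacements — the raw material of the entropy descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    InsufficientBoundaryError,
    LagTooLargeError,
    ZeroRadiusError,
)
from .imaging import Boundary

#: Default lag per object scale (boundary smoothing stride): single cells
#: sit at dN=4, nuclei and cell pairs at dN=2, spheroids at dN=5.
DEFAULT_LAG = {"cell": 4, "nucleus": 2, "spheroid": 5}


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of one CME analysis.

    Parameters
    ----------
    dN
        Boundary subsampling lag (>= 1). See :data:`DEFAULT_LAG` for the
        per-scale conventions.
    n_bins
        Histogram bin count for both displacement components (>= 2).  The
        entropy is normalized by ``log2(n_bins)``, so this must be held
        fixed for values to be comparable across frames and objects.
    bin_range_mode
        ``"fixed"`` (default) bins each component over a fixed range in its
        natural units — ``dr`` in units of the mean radius, ``dtheta`` in
        units of the mean angular step ``2 pi / N`` — so the descriptor is
        scale- and rotation-invariant yet still responds to feature
        amplitude; outliers are clipped into the edge bins.
        ``"per_frame"`` bins each frame over its own [min, max] (shape of
        the distribution only); ``"global"`` uses one min-max range across
        a whole time series.
    smoothing_radius
        Gaussian sigma (px) applied before thresholding; 0 disables.
    min_area
        Minimum object area in px² accepted by mask cleaning.
    seed
        Seed forwarded to stochastic downstream steps (e.g. clustering).
    """

    dN: int = 2
    n_bins: int = 16
    bin_range_mode: str = "fixed"
    smoothing_radius: float = 1.0
    min_area: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dN < 1:
            raise ValueError("dN must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.bin_range_mode not in ("fixed", "per_frame", "global"):
            raise ValueError(
                "bin_range_mode must be 'fixed', 'per_frame' or 'global'")


@dataclass(frozen=True)
class PolarBoundary:
    """Boundary samples ``(r_j, theta_j)`` about the centroid, in traced
    order; ``lag_applied`` records the subsampling stride (1 = raw)."""

    r: np.ndarray
    theta: np.ndarray
    lag_applied: int = 1

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        t = np.asarray(self.theta, dtype=float)
        if r.shape != t.shape or r.ndim != 1:
            raise ValueError("r and theta must be equal-length 1-D arrays")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "theta", t)

    @property
    def N(self) -> int:
        return int(self.r.size)


@dataclass(frozen=True)
class DisplacementSeries:
    """Consecutive boundary displacements: radial ``dr`` and angular
    ``dtheta`` (wrapped to (-pi, pi]); ``m`` displacement pairs.

    ``r_mean`` (mean radius of the generating boundary) and
    ``dtheta_step`` (mean angular step ``2 pi / N`` of a closed boundary)
    are carried along as the natural normalization scales of the two
    components; they stay ``None`` for hand-built series.
    """

    dr: np.ndarray
    dtheta: np.ndarray
    r_mean: float | None = None
    dtheta_step: float | None = None

    def __post_init__(self) -> None:
        dr = np.asarray(self.dr, dtype=float)
        dt = np.asarray(self.dtheta, dtype=float)
        if dr.shape != dt.shape or dr.ndim != 1:
            raise ValueError("dr and dtheta must be equal-length 1-D arrays")
        object.__setattr__(self, "dr", dr)
        object.__setattr__(self, "dtheta", dt)

    @property
    def m(self) -> int:
        return int(self.dr.size)


def wrap_angle(delta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angular differences into (-pi, pi] (minimal signed difference).

    Consecutive traced boundary points subtend small angles; without
    wrapping, steps across the ±pi cut would inject spurious ±2pi outliers
    into the angular-displacement histogram.
    """
    d = np.asarray(delta, dtype=float)
    w = np.mod(d + np.pi, 2.0 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return float(w) if np.isscalar(delta) else w


def to_polar(boundary: Boundary) -> PolarBoundary:
    """Map a Cartesian boundary into polar coordinates about its centroid.

    ``r_i`` is the Euclidean distance to the centroid; ``theta_i`` is the
    mathematical-convention angle (counterclockwise positive, obtained by
    negating the image-frame ``y``).  Point ordering is preserved.

    Raises
    ------
    ZeroRadiusError
        If any point coincides with the centroid.
    """
    cx, cy = boundary.centroid
    dx = boundary.points[:, 0] - cx
    dy = -(boundary.points[:, 1] - cy) + 0.0  # image y-down -> math y-up
    r = np.hypot(dx, dy)
    if np.any(r == 0):
        raise ZeroRadiusError("zero radius: boundary point at centroid")
    theta = np.arctan2(dy, dx)
    theta[theta == -np.pi] = np.pi  # angles live in (-pi, pi]
    return PolarBoundary(r=r, theta=theta, lag_applied=1)


def subsample_lag(pb: PolarBoundary, dN: int) -> PolarBoundary:
    """Keep points at 1-based indices ``dN, 2 dN, ..., floor(N/dN) * dN``.

    ``dN = 1`` is the identity.  Raises :class:`LagTooLargeError` when the
    boundary has fewer than ``2 * dN`` points (subsampling would leave a
    single point).
    """
    if dN < 1:
        raise ValueError("dN must be >= 1")
    N = pb.N
    if N < 2 * dN:
        raise LagTooLargeError(f"lag too large for boundary: N={N}, dN={dN}")
    idx = np.arange(1, N // dN + 1) * dN - 1  # 1-based dN, 2dN, ... -> 0-based
    return PolarBoundary(r=pb.r[idx], theta=pb.theta[idx], lag_applied=dN)


def displacements(pb: PolarBoundary) -> DisplacementSeries:
    """Consecutive displacements along the (subsampled) boundary.

    ``dr_j = r_j - r_{j-1}``; ``dtheta_j`` is the wrapped difference of
    consecutive angles.  The chain is open: ``m = N - 1`` displacements,
    with no closing last-to-first term.
    """
    if pb.N < 2:
        raise InsufficientBoundaryError("insufficient boundary: need >= 2 points")
    dr = np.diff(pb.r)
    dtheta = wrap_angle(np.diff(pb.theta))
    return DisplacementSeries(
        dr=dr, dtheta=dtheta,
        r_mean=float(pb.r.mean()),
        dtheta_step=2.0 * np.pi / pb.N,
    )


def boundary_displacements(boundary: Boundary, dN: int) -> DisplacementSeries:
    """Convenience: polar map, lag-subsample, difference."""
    return displacements(subsample_lag(to_polar(boundary), dN))
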