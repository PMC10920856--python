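"""Seeded generators of analytic boundaries, rasterized masks, and
time-lapse scenarios, so the whole pipeline is testable without any
external imagery.

Shape families
--------------
All shapes are star-convex radial functions ``r(phi) = base * (1 + sum of
bumps + noise)`` sampled at equally spaced angles (ellipses and rods use
their analytic radial forms instead):

* ``circle`` / ``ellipse`` / ``rod`` — regular outlines; ``rod`` is a
  flat-sided superellipse emulating a nucleus elongated in a channel.
* ``blebby`` — many small raised-cosine bumps: the rounded, bleb-covered
  outline of ameboid migration.
* ``protrusive`` — few large protrusions: the elongated mesenchymal
  outline with distinct leading/trailing extensions.
* ``fingered_spheroid`` — a disk sprouting narrow invasion strands
  ("fingers") of individually controlled lengths.

Scenarios
---------
``make_scene`` builds three mask stacks with ground truth emitted
alongside, emulating the experimental settings the descriptor is meant
for: a nucleus squeezing through a chamber/channel array of increasing
confinement (``squeeze``), a pair of cells whose protrusion activity
alternates in antiphase (``pair``), and a spheroid that grows and then
sprouts fingers after a planted transition time (``spheroid``).

All generators are pure functions of their spec: same spec + same seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .exceptions import CMEError, DegenerateObjectError
from .imaging import BinaryMask, Boundary


# ---------------------------------------------------------------------------
# Analytic shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSpec:
    """Specification of one analytic outline (units: pixels, radians)."""

    family: str = "circle"
    base_radius: float = 40.0
    aspect_ratio: float = 1.0           # ellipse / rod
    n_bumps: int = 0                    # blebby / protrusive / fingers
    bump_amplitude: float = 0.0         # fraction of base_radius
    bump_width: float | None = None     # half-width (rad); default pi/n_bumps
    finger_lengths: tuple[float, ...] | None = None  # fractions, per finger
    n_samples: int = 720
    noise_sd: float = 0.0               # fractional, smooth correlated noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in (
            "circle", "ellipse", "rod", "blebby", "protrusive",
            "fingered_spheroid",
        ):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_samples < 32:
            raise ValueError("n_samples must be >= 32")
        if self.bump_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")


def _raised_cosine(dphi: np.ndarray, half_width: float) -> np.ndarray:
    """Smooth bump: 0.5 * (1 + cos(pi * d / w)) on |d| < w, else 0."""
    out = np.zeros_like(dphi)
    inside = np.abs(dphi) < half_width
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * dphi[inside] / half_width))
    return out


def _wrap(d: np.ndarray) -> np.ndarray:
    return np.mod(d + np.pi, 2.0 * np.pi) - np.pi


def make_shape(spec: ShapeSpec) -> np.ndarray:
    """Sample the outline as an ``(n, 2)`` polygon in mathematical
    coordinates (y up), counterclockwise, centered near the origin."""
    rng = np.random.default_rng(spec.seed)
    phi = np.linspace(0.0, 2.0 * np.pi, spec.n_samples, endpoint=False)
    base = spec.base_radius

    if spec.family in ("ellipse", "rod"):
        a = base * spec.aspect_ratio  # semi-major
        b = base                      # semi-minor
        if spec.family == "ellipse":
            r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        else:  # superellipse exponent 4: flat-sided, capsule-like
            r = (np.abs(np.cos(phi) / a) ** 4
                 + np.abs(np.sin(phi) / b) ** 4) ** (-0.25)
    else:
        bump_total = np.zeros_like(phi)
        if spec.family in ("blebby", "protrusive") and spec.n_bumps > 0:
            k = spec.n_bumps
            width = spec.bump_width if spec.bump_width is not None else np.pi / k
            phase = rng.uniform(0.0, 2.0 * np.pi)
            jitter_scale = 0.0 if spec.family == "blebby" else 0.12
            for i in range(k):
                center = phase + 2.0 * np.pi * i / k \
                    + jitter_scale * rng.normal()
                amp = spec.bump_amplitude * (0.75 + 0.5 * rng.random())
                bump_total += amp * _raised_cosine(_wrap(phi - center), width)
        elif spec.family == "fingered_spheroid":
            lengths = spec.finger_lengths or ()
            k = max(len(lengths), 1)
            width = spec.bump_width if spec.bump_width is not None else 0.18
            phase = rng.uniform(0.0, 2.0 * np.pi)
            for i, frac in enumerate(lengths):
                center = phase + 2.0 * np.pi * i / k + 0.1 * rng.normal()
                bump_total += frac * _raised_cosine(_wrap(phi - center), width)
        r = base * (1.0 + bump_total)

    if spec.noise_sd > 0:
        r = r * (1.0 + spec.noise_sd * _smooth_noise(rng, spec.n_samples))
    if np.any(r <= 0):
        raise ValueError("shape parameters produce a non-positive radius")
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _smooth_noise(rng: np.random.Generator, n: int, corr: int = 9) -> np.ndarray:
    """Unit-sd correlated noise: circular moving average of white noise."""
    w = rng.standard_normal(n)
    kernel = np.ones(corr) / corr
    sm = np.real(np.fft.ifft(np.fft.fft(w) * np.fft.fft(kernel, n)))
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def boundary_from_polygon(polygon: np.ndarray) -> Boundary:
    """Wrap an analytic polygon (math coords) as a :class:`Boundary`.

    Converts to the package's image convention (y down) and uses the
    polygon area centroid, so analytic shapes can enter the polar pipeline
    without rasterization.
    """
    poly = np.asarray(polygon, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise DegenerateObjectError("degenerate object: zero-area polygon")
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    pts = np.column_stack([x, -y])  # math -> image convention
    return Boundary(points=pts, centroid=(float(cx), float(-cy)),
                    area=float(abs(area)), closed=True)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(
    polygon: np.ndarray,
    image_size: int | tuple[int, int],
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Fill a polygon into a mask: a pixel is foreground iff its center
    lies inside the polygon.

    The polygon (math coords, pixel units, centered near 0) is placed at
    the image center; ``y`` is flipped into the raster convention.
    """
    shape = (image_size, image_size) if np.isscalar(image_size) else tuple(image_size)
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cols = cx + polygon[:, 0]
    rows = cy - polygon[:, 1]
    if (cols.min() < 0 or cols.max() > w - 1
            or rows.min() < 0 or rows.max() > h - 1):
        raise ValueError("polygon exceeds image bounds")
    r0, r1 = int(np.floor(rows.min())), int(np.ceil(rows.max()))
    c0, c1 = int(np.floor(cols.min())), int(np.ceil(cols.max()))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                         indexing="ij")
    centers = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    inside = MplPath(np.column_stack([cols, rows])).contains_points(centers)
    mask = np.zeros(shape, dtype=bool)
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    if not mask.any():
        raise CMEError("degenerate: polygon covers no pixel center")
    return BinaryMask(mask, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Time-lapse scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Specification of one synthetic time-lapse scenario.

    Geometry defaults for ``squeeze`` follow the micro-structured array the
    descriptor was designed around: four channels (18 µm long) narrowing
    from 11.2 to 1.7 µm, separated by three 23-µm chambers, traversed at
    constant speed by a nucleus of ~14 µm equivalent diameter.  The
    ``spheroid`` scenario grows a disk and sprouts fingers after
    ``transition_frac`` of the observation window; ``pair`` alternates the
    protrusion amplitude of two cells in antiphase.
    """

    scenario: str = "spheroid"
    n_frames: int = 40
    frame_interval: float | None = None  # minutes; scenario default if None
    image_size: int | None = None
    pixel_size: float | None = None      # µm/px; scenario default if None
    seed: int = 0
    noise_sd: float = 0.01
    # squeeze geometry (µm): the four traversed channels pinch the nucleus
    # to rod widths narrowing from 8.4 to 6.6 µm (the wider array tapers
    # from 11.2 to 1.7 µm overall; only this stretch is emulated)
    channel_width_start: float = 8.4
    channel_width_end: float = 6.6
    chamber_length: float = 23.0
    channel_length: float = 18.0
    n_channels: int = 4
    nucleus_diameter: float = 14.0
    max_aspect_ratio: float = 4.5
    # pair
    alternation_period: float = 60.0    # minutes
    protrusion_base: float = 0.35
    protrusion_swing: float = 0.25
    # spheroid
    initial_radius_um: float = 150.0
    growth_per_frame: float = 0.004     # fractional radius growth per frame
    transition_frac: float = 0.6
    n_fingers: int = 8
    finger_growth: float = 0.035        # max-finger fraction gained per frame

    #: per-scenario (frame_interval min, image_size px, pixel_size µm/px):
    #: nuclei are imaged fast at high resolution, cell pairs at moderate
    #: resolution, spheroids slowly at low resolution.
    SCENARIO_DEFAULTS = {
        "squeeze": (5.0, 160, 0.25),
        "pair": (2.0, 128, 1.0),
        "spheroid": (60.0, 192, 3.0),
    }

    def __post_init__(self) -> None:
        if self.scenario not in ("squeeze", "pair", "spheroid"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        dt, size, ps = self.SCENARIO_DEFAULTS[self.scenario]
        if self.frame_interval is None:
            object.__setattr__(self, "frame_interval", dt)
        if self.image_size is None:
            object.__setattr__(self, "image_size", size)
        if self.pixel_size is None:
            object.__setattr__(self, "pixel_size", ps)


@dataclass(frozen=True)
class Scene:
    """Mask stacks keyed by object label, plus the ground-truth table."""

    stacks: dict[str, list[BinaryMask]]
    truth: pd.DataFrame
    spec: SceneSpec

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.spec.n_frames) * self.spec.frame_interval


def make_scene(spec: SceneSpec) -> Scene:
    """Build the scenario's mask stack(s) and ground-truth table."""
    if spec.scenario == "squeeze":
        return _squeeze_scene(spec)
    if spec.scenario == "pair":
        return _pair_scene(spec)
    return _spheroid_scene(spec)


def _squeeze_scene(spec: SceneSpec) -> Scene:
    """Nucleus traversing chambers and channels at constant speed.

    The structure sequence is channel, chamber, ..., channel (``n_channels``
    channels, ``n_channels - 1`` chambers).  In a channel narrower than the
    nucleus the target elongation is ``diameter / width`` (area-conserving
    rod, capped at ``max_aspect_ratio``); in a chamber the nucleus relaxes
    back toward round.  Shape responds with first-order relaxation so that
    entering/exiting a channel is gradual.
    """
    rng = np.random.default_rng(spec.seed)
    widths = np.linspace(spec.channel_width_start, spec.channel_width_end,
                         spec.n_channels)
    # half-length entry/exit chambers bracket the channel run, so every
    # channel passage shows up as an interior peak of the CME profile
    segments: list[tuple[str, int, float]] = []  # (kind, channel_idx, length)
    segments.append(("chamber", -1, spec.chamber_length / 2.0))
    for k in range(spec.n_channels):
        segments.append(("channel", k, spec.channel_length))
        if k < spec.n_channels - 1:
            segments.append(("chamber", -1, spec.chamber_length))
    segments.append(("chamber", -1, spec.chamber_length / 2.0))
    total = sum(s[2] for s in segments)
    edges = np.cumsum([0.0] + [s[2] for s in segments])

    d0 = spec.nucleus_diameter
    base_r_px = (d0 / 2.0) / spec.pixel_size
    masks: list[BinaryMask] = []
    rows = []
    ar = 1.05
    for f in range(spec.n_frames):
        s = (f + 0.5) / spec.n_frames * total  # arc-length position
        idx = int(np.searchsorted(edges, s, side="right")) - 1
        kind, ch_idx, _ = segments[min(idx, len(segments) - 1)]
        if kind == "channel":
            w_eff = min(widths[ch_idx], d0)
            target = float(np.clip(d0 / w_eff, 1.05, spec.max_aspect_ratio))
        else:
            target = 1.05
        ar += (target - ar) * 0.6  # first-order shape relaxation
        b_px = base_r_px / np.sqrt(ar)  # area-conserving semi-minor
        shape = ShapeSpec(
            family="rod", base_radius=b_px, aspect_ratio=ar,
            noise_sd=spec.noise_sd, n_samples=720,
            seed=int(rng.integers(2**31 - 1)),
        )
        masks.append(rasterize(make_shape(shape), spec.image_size,
                               spec.pixel_size))
        rows.append({
            "frame": f,
            "time_min": f * spec.frame_interval,
            "structure": kind,
            "channel_index": ch_idx,
            "channel_width_um": widths[ch_idx] if kind == "channel" else np.nan,
            "target_ar": target,
            "ar": ar,
        })
    return Scene(stacks={"nucleus": masks}, truth=pd.DataFrame(rows), spec=spec)


def _pair_scene(spec: SceneSpec) -> Scene:
    """Two cells whose protrusion amplitudes alternate in antiphase."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.frame_interval
    osc = np.sin(2.0 * np.pi * t / spec.alternation_period)
    base_r_px = 18.0
    stacks: dict[str, list[BinaryMask]] = {"up": [], "down": []}
    rows = []
    for f in range(spec.n_frames):
        amps = {
            "up": spec.protrusion_base + spec.protrusion_swing * osc[f],
            "down": spec.protrusion_base - spec.protrusion_swing * osc[f],
        }
        for label, amp in amps.items():
            shape = ShapeSpec(
                family="protrusive", base_radius=base_r_px,
                n_bumps=2, bump_amplitude=max(amp, 0.02), bump_width=0.45,
                noise_sd=spec.noise_sd, n_samples=720,
                seed=int(rng.integers(2**31 - 1)),
            )
            stacks[label].append(
                rasterize(make_shape(shape), spec.image_size, spec.pixel_size))
        rows.append({
            "frame": f, "time_min": t[f],
            "amp_up": amps["up"], "amp_down": amps["down"],
        })
    return Scene(stacks=stacks, truth=pd.DataFrame(rows), spec=spec)


def _spheroid_scene(spec: SceneSpec) -> Scene:
    """Disk growth (proliferation) then finger sprouting (invasion).

    Before the planted transition frame the outline is a noisy disk whose
    radius grows a little each frame; afterwards ``n_fingers`` strands
    grow linearly with per-finger rate multipliers.  The transition time
    is emitted in the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    trans_frame = int(round(spec.transition_frac * (spec.n_frames - 1)))
    rates = 0.5 + rng.random(spec.n_fingers)  # per-finger growth multipliers
    r_px = spec.initial_radius_um / spec.pixel_size
    max_r = (spec.image_size / 2.0) - 6.0
    masks: list[BinaryMask] = []
    rows = []
    for f in range(spec.n_frames):
        radius = min(r_px * (1.0 + spec.growth_per_frame * f), 0.7 * max_r)
        if f > trans_frame:
            lengths = tuple(
                np.minimum(spec.finger_growth * (f - trans_frame) * rates, 0.38)
            )
        else:
            lengths = None
        if lengths is not None and max(lengths) * radius + radius > max_r:
            lengths = tuple(min(x, (max_r - radius) / radius) for x in lengths)
        shape = ShapeSpec(
            family="fingered_spheroid", base_radius=radius,
            n_bumps=spec.n_fingers, finger_lengths=lengths,
            noise_sd=0.0, n_samples=720,
            seed=spec.seed,  # fixed finger placement across frames
        )
        poly = make_shape(shape)
        if spec.noise_sd > 0:  # per-frame independent boundary noise
            jitter = ShapeSpec(
                family="circle", base_radius=1.0, noise_sd=spec.noise_sd,
                n_samples=720, seed=int(rng.integers(2**31 - 1)),
            )
            noise_r = np.hypot(*make_shape(jitter).T)
            poly = poly * noise_r[:, None]
        masks.append(rasterize(poly, spec.image_size, spec.pixel_size))
        rows.append({
            "frame": f,
            "time_min": f * spec.frame_interval,
            "phase": "invasion" if f > trans_frame else "proliferation",
            "radius_um": radius * spec.pixel_size,
            "max_finger_frac": 0.0 if lengths is None else float(max(lengths)),
            "transition_frame": trans_frame,
            "transition_time_min": trans_frame * spec.frame_interval,
        })
    return Scene(stacks={"spheroid": masks}, truth=pd.DataFrame(rows), spec=spec)


# ---------------------------------------------------------------------------
# Fixture helpers
# ---------------------------------------------------------------------------

def make_mode_masks(
    mode: str,
    n: int,
    seed: int = 0,
    base_radius: float = 40.0,
    image_size: int = 160,
) -> list[BinaryMask]:
    """Rasterized single-cell outlines of one migration mode.

    ``"ameboid"`` gives rounded outlines with 12 small blebs (5% of the
    radius); ``"mesenchymal"`` gives outlines with 2 large protrusions
    (60% of the radius).  Each mask gets its own derived seed.
    """
    if mode == "ameboid":
        proto = ShapeSpec(family="blebby", base_radius=base_radius,
                          n_bumps=12, bump_amplitude=0.05, noise_sd=0.01)
    elif mode == "mesenchymal":
        proto = ShapeSpec(family="protrusive", base_radius=base_radius,
                          n_bumps=2, bump_amplitude=0.60, bump_width=0.45,
                          noise_sd=0.01)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    masks = []
    for i in range(n):
        spec = replace(proto, seed=seed * 10_000 + i)
        masks.append(rasterize(make_shape(spec), image_size))
    return masks
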