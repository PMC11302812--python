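"""Synthetic portal-image generator with known ground-truth delays.

Renders the high-contrast metal-ball projection of a Winston-Lutz-type
cube on a uniform background:

* a **static reference** image with the ball at the gate reference
  position;
* a **beam-on snapshot** (minimal-MU exposure treated as instantaneous)
  with the ball displaced along the motion direction by
  ``velocity * true_delay``;
* a **beam-off blur trace**: the footprint swept by the moving ball while
  the beam is on, ending at the stop position displaced from the beam-off
  reference by ``velocity * true_delay``.

The ball is modelled as an opaque disk; the trace is rendered in the
saturated high-contrast limit, i.e. the swept region (a stadium shape:
a rectangle with semicircular caps) carries the full attenuation depth.
In this limit the trace's stop-side edge has exactly the static ball's
edge profile, which is the property the beam-off matching algorithm
exploits.  An optional linear intensity ramp-down over the final
``ramp_time`` of travel models a soft dose-rate cutoff.

All positions in scenario parameters are mm at the isocenter plane; the
renderer applies the projective magnification.  The motion axis is the
image column axis, with positions increasing with column index, so
descending phantom motion moves the ball toward lower columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import GeometryError, InvalidInputError
from .geometry import BeamGeometry
from .images import PortalImage
from .motion import Direction, direction_sign

_SUPERSAMPLE = 16  # sub-pixel grid per axis for area-weighted edge coverage


@dataclass(frozen=True)
class BallSpec:
    """Physical ball footprint at the isocenter plane.

    ``contrast`` is the fractional attenuation at the ball center
    (1 = fully opaque); ``background_level`` is the open-field detector
    signal in counts.
    """

    diameter: float = 6.0
    contrast: float = 0.8
    background_level: float = 10000.0

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise InvalidInputError("ball diameter must be positive")
        if not 0 < self.contrast <= 1:
            raise InvalidInputError("contrast must be in (0, 1]")
        if not self.background_level > 0:
            raise InvalidInputError("background_level must be positive")


@dataclass(frozen=True)
class SimScenario:
    """One simulated acquisition with known ground truth.

    ``reference_position`` is the gate reference (mm, isocenter plane):
    the beam-on reference for snapshot scenarios, the beam-off reference
    for trace scenarios.  ``true_delay`` is the ground-truth latency in ms.
    """

    geometry: BeamGeometry = BeamGeometry()
    ball: BallSpec = BallSpec()
    velocity: float = 24.0
    true_delay: float = 0.0
    phase: Literal["beam_on", "beam_off"] = "beam_on"
    reference_position: float = 0.0
    direction: Direction = "descending"
    beam_duration: float = 0.8
    ramp_time: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.velocity > 0:
            raise InvalidInputError("velocity must be positive")
        if self.true_delay < 0:
            raise InvalidInputError("true_delay must be >= 0")
        if self.phase not in ("beam_on", "beam_off"):
            raise InvalidInputError(f"bad phase {self.phase!r}")
        if self.ramp_time < 0 or self.noise_sigma < 0:
            raise InvalidInputError("ramp_time and noise_sigma must be >= 0")
        if self.phase == "beam_off":
            if not self.beam_duration > 0:
                raise InvalidInputError("beam_duration must be positive for beam_off")
            if self.beam_duration * self.velocity < self.ball.diameter:
                raise InvalidInputError(
                    "beam-off travel must cover at least one ball diameter"
                )


def _subpixel_offsets() -> np.ndarray:
    ss = _SUPERSAMPLE
    return (np.arange(ss) + 0.5) / ss - 0.5


def _footprint_check(lo_px: float, hi_px: float, n: int, what: str) -> None:
    if lo_px < -0.5 or hi_px > n - 0.5:
        raise GeometryError(
            f"{what} footprint [{lo_px:.1f}, {hi_px:.1f}] px exceeds image extent (n={n})"
        )


def _disk_coverage(
    shape: tuple[int, int], row_c: float, col_c: float, radius_px: float
) -> np.ndarray:
    """Per-pixel area coverage fraction of a disk, by sub-pixel sampling."""
    nr, nc = shape
    _footprint_check(row_c - radius_px, row_c + radius_px, nr, "ball (rows)")
    _footprint_check(col_c - radius_px, col_c + radius_px, nc, "ball (cols)")
    r0 = max(int(np.floor(row_c - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(row_c + radius_px)) + 2, nr)
    c0 = max(int(np.floor(col_c - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(col_c + radius_px)) + 2, nc)
    off = _subpixel_offsets()
    dr2 = (np.arange(r0, r1)[:, None] + off[None, :] - row_c) ** 2
    dc2 = (np.arange(c0, c1)[:, None] + off[None, :] - col_c) ** 2
    inside = dr2[:, None, :, None] + dc2[None, :, None, :] <= radius_px**2
    cov = np.zeros(shape)
    cov[r0:r1, c0:c1] = inside.mean(axis=(2, 3))
    return cov


def _stadium_coverage(
    shape: tuple[int, int],
    row_c: float,
    col_a: float,
    col_b: float,
    radius_px: float,
    ramp_px: float = 0.0,
    stop_col: float | None = None,
    motion_sign: float = 1.0,
) -> np.ndarray:
    """Coverage of the region swept by a disk translated from col_a to col_b.

    With ``ramp_px > 0`` the coverage is weighted by a linear intensity
    ramp that falls from 1 to 0 over the final ``ramp_px`` of travel
    toward ``stop_col``.
    """
    nr, nc = shape
    lo, hi = min(col_a, col_b), max(col_a, col_b)
    _footprint_check(row_c - radius_px, row_c + radius_px, nr, "trace (rows)")
    _footprint_check(lo - radius_px, hi + radius_px, nc, "trace (cols)")
    r0 = max(int(np.floor(row_c - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(row_c + radius_px)) + 2, nr)
    c0 = max(int(np.floor(lo - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(hi + radius_px)) + 2, nc)
    off = _subpixel_offsets()
    rows = np.arange(r0, r1)[:, None] + off[None, :]  # (nr_b, ss)
    cols = np.arange(c0, c1)[:, None] + off[None, :]  # (nc_b, ss)
    dr2 = (rows - row_c) ** 2
    dcols = cols - np.clip(cols, lo, hi)
    inside = dr2[:, None, :, None] + (dcols**2)[None, :, None, :] <= radius_px**2
    if ramp_px > 0:
        assert stop_col is not None
        # distance still to travel before the stop, along the motion direction
        remaining = motion_sign * (stop_col - cols)
        w = np.clip(remaining / ramp_px, 0.0, 1.0)[None, :, None, :]
        block = (inside * w).mean(axis=(2, 3))
    else:
        block = inside.mean(axis=(2, 3))
    cov = np.zeros(shape)
    cov[r0:r1, c0:c1] = block
    return cov


def _finish(scenario: SimScenario, coverage: np.ndarray) -> PortalImage:
    ball = scenario.ball
    img = ball.background_level * (1.0 - ball.contrast * coverage)
    if scenario.noise_sigma > 0:
        rng = np.random.default_rng(scenario.seed)
        img = img + rng.normal(0.0, scenario.noise_sigma, img.shape)
        np.clip(img, 0.0, None, out=img)
    return PortalImage(img, scenario.geometry.pixel_pitch, "cols")


def _ball_radius_px(scenario: SimScenario) -> float:
    g = scenario.geometry
    return scenario.ball.diameter / 2.0 * g.magnification / g.pixel_pitch


def _pos_to_col(scenario: SimScenario, pos_iso_mm: float) -> float:
    g = scenario.geometry
    nc = g.image_shape[1]
    return (nc - 1) / 2.0 + pos_iso_mm * g.magnification / g.pixel_pitch


def render_reference(scenario: SimScenario) -> PortalImage:
    """Static reference image: ball at ``reference_position``."""
    g = scenario.geometry
    row_c = (g.image_shape[0] - 1) / 2.0
    col_c = _pos_to_col(scenario, scenario.reference_position)
    cov = _disk_coverage(g.image_shape, row_c, col_c, _ball_radius_px(scenario))
    return _finish(scenario, cov)


def render_beam_on_snapshot(scenario: SimScenario) -> PortalImage:
    """Beam-on snapshot: ball displaced by ``velocity * true_delay`` along motion."""
    if scenario.phase != "beam_on":
        raise InvalidInputError("render_beam_on_snapshot requires phase='beam_on'")
    g = scenario.geometry
    s = direction_sign(scenario.direction)
    pos = scenario.reference_position + s * scenario.velocity * scenario.true_delay / 1000.0
    row_c = (g.image_shape[0] - 1) / 2.0
    cov = _disk_coverage(
        g.image_shape, row_c, _pos_to_col(scenario, pos), _ball_radius_px(scenario)
    )
    return _finish(scenario, cov)


def render_beam_off_trace(scenario: SimScenario) -> PortalImage:
    """Beam-off blur trace ending past the reference by ``velocity * true_delay``."""
    if scenario.phase != "beam_off":
        raise InvalidInputError("render_beam_off_trace requires phase='beam_off'")
    g = scenario.geometry
    s = direction_sign(scenario.direction)
    stop = scenario.reference_position + s * scenario.velocity * scenario.true_delay / 1000.0
    start = stop - s * scenario.velocity * scenario.beam_duration
    row_c = (g.image_shape[0] - 1) / 2.0
    col_start = _pos_to_col(scenario, start)
    col_stop = _pos_to_col(scenario, stop)
    ramp_px = scenario.velocity * scenario.ramp_time / 1000.0 * g.magnification / g.pixel_pitch
    cov = _stadium_coverage(
        g.image_shape,
        row_c,
        col_start,
        col_stop,
        _ball_radius_px(scenario),
        ramp_px=ramp_px,
        stop_col=col_stop,
        motion_sign=s,
    )
    return _finish(scenario, cov)


def render_pair(scenario: SimScenario) -> tuple[PortalImage, PortalImage]:
    """Render (reference, motion) for a scenario; motion is snapshot or trace."""
    ref = render_reference(replace(scenario, seed=scenario.seed + 1))
    if scenario.phase == "beam_on":
        return ref, render_beam_on_snapshot(scenario)
    return ref, render_beam_off_trace(scenario)
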