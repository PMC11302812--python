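"""Conversion of detected ball positions into beam time delays.

The core relations are

    t = dx / v          (delay from displacement)
    dx = P_meas - P_ref (ball displacement)

with ``P_meas`` and ``P_ref`` measured at the detector plane and divided
by the projective magnification SID/SAD to obtain the physical
displacement at the isocenter plane.  Displacements along the phantom's
motion direction are positive; a negative delay (ball short of the
reference) is reported, not clamped.

Beam-off delays cannot use a single ball position because the moving
ball leaves an elongated blur trace.  Instead the static reference ball
profile is "intentionally displaced" along the motion direction: for each
candidate displacement the reference edge template is compared against
the trace's stop-side edge by sum of squared differences, and the best
match gives the stop position.  An independent 50%-crossing edge
estimate serves as a diagnostic cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .errors import InvalidInputError, QualityWarning, SearchRangeError
from .geometry import BeamGeometry
from .images import PortalImage
from .locate import (
    _attenuation,
    _auto_band,
    _cross_left,
    _cross_right,
    extract_profile,
    locate_ball_center,
    locate_trace_edges,
)
from .motion import Direction, direction_sign

COARSE_STEP_PX = 0.25
FINE_STEP_PX = 0.05
DEFAULT_SEARCH_MM = (0.0, 15.0)  # isocenter plane; spans delays well past 310 ms at 24 mm/s
PLAUSIBLE_DELAY_MS = 1000.0


@dataclass(frozen=True)
class DelayMeasurement:
    """One repeat's displacement and delay.

    ``delta_x`` is mm at the isocenter plane (positive along the motion
    direction), ``velocity`` in mm/s, ``delay`` in ms.
    """

    delta_x: float
    velocity: float
    delay: float
    phase: Literal["beam_on", "beam_off"]
    repeat_index: int = 0
    beam_mode: str = ""

    def __post_init__(self) -> None:
        if not self.velocity > 0:
            raise InvalidInputError("velocity must be positive")
        expected = self.delta_x / self.velocity * 1000.0
        if abs(self.delay - expected) > 1e-9 * max(1.0, abs(expected)):
            raise InvalidInputError(
                f"inconsistent delay: {self.delay} ms vs delta_x/v = {expected} ms"
            )


def displacement_isocenter(
    p_meas: float, p_ref: float, geometry: BeamGeometry
) -> float:
    """Back-project a detector-plane displacement to the isocenter plane.

    Returns ``(p_meas - p_ref) * sad / sid`` with the sign preserved.
    """
    return (p_meas - p_ref) * geometry.sad / geometry.sid


def delay_from_displacement(delta_x: float, velocity: float) -> float:
    """Delay in ms from an isocenter-plane displacement in mm: t = dx / v."""
    if not velocity > 0:
        raise InvalidInputError(f"velocity must be positive, got {velocity}")
    return delta_x / velocity * 1000.0


def _measurement(
    delta_x: float,
    velocity: float,
    phase: Literal["beam_on", "beam_off"],
    repeat_index: int,
    beam_mode: str,
) -> DelayMeasurement:
    delay = delay_from_displacement(delta_x, velocity)
    if abs(delay) > PLAUSIBLE_DELAY_MS:
        warnings.warn(
            f"|delay| = {abs(delay):.0f} ms exceeds {PLAUSIBLE_DELAY_MS:.0f} ms; "
            "check setup (velocity, direction, reference)",
            QualityWarning,
            stacklevel=3,
        )
    return DelayMeasurement(
        delta_x=delta_x,
        velocity=velocity,
        delay=delay,
        phase=phase,
        repeat_index=repeat_index,
        beam_mode=beam_mode,
    )


def beam_on_delay(
    reference: PortalImage,
    motion: PortalImage,
    geometry: BeamGeometry,
    velocity: float,
    direction: Direction = "descending",
    repeat_index: int = 0,
    beam_mode: str = "",
) -> DelayMeasurement:
    """Beam-on delay from a reference/snapshot image pair.

    Locates the ball in both images, converts the detector-plane
    displacement to the isocenter plane, orients it along the motion
    direction, and divides by the velocity.
    """
    p_ref = locate_ball_center(reference).center
    p_meas = locate_ball_center(motion).center
    s = direction_sign(direction)
    delta_x = s * displacement_isocenter(p_meas, p_ref, geometry)
    return _measurement(delta_x, velocity, "beam_on", repeat_index, beam_mode)


def beam_off_objective(
    reference: PortalImage,
    trace: PortalImage,
    geometry: BeamGeometry,
    direction: Direction = "descending",
    band_halfwidth: int | None = None,
) -> tuple[Callable[[float], float], dict]:
    """Build the stop-side shift-and-match SSD objective.

    For a candidate displacement ``d`` (mm, isocenter plane, along the
    motion direction) the normalized reference ball profile — extended to
    a plateau on its trailing side, because the trace interior is swept —
    is centered at ``P_ref + sign * d * M`` and compared by sum of squared
    differences against the normalized trace profile over a fixed window
    from the trace mid-plateau to just beyond the stop edge.

    Returns the objective and a dict of intermediate quantities
    (``p_ref``, ``lead_edge``, ``stop_edge``, ``ref_stop_crossing``).
    """
    s = direction_sign(direction)
    mag = geometry.magnification
    if band_halfwidth is None:
        band_halfwidth = _auto_band(reference)

    ref_det = locate_ball_center(reference, band_halfwidth)
    ref_profile = extract_profile(reference, band_halfwidth)
    ref_attn, _ = _attenuation(ref_profile)
    ref_norm = ref_attn / ref_det.depth
    u_ref = s * (ref_profile.positions - ref_det.center)
    order = np.argsort(u_ref)
    u_sorted, ref_sorted = u_ref[order], ref_norm[order]

    trace_profile = extract_profile(trace, band_halfwidth)
    trace_attn, _ = _attenuation(trace_profile)
    depth_t = float(trace_attn.max())
    plateau = float(np.median(trace_attn[trace_attn >= 0.7 * depth_t]))
    trace_norm = trace_attn / plateau

    lead, stop = locate_trace_edges(trace, direction)
    mid = (lead + stop) / 2.0
    margin = ref_det.fwhm
    x = trace_profile.positions
    mask = (s * (x - mid) >= 0) & (s * (x - stop) <= margin)
    x_win = x[mask]
    trace_win = trace_norm[mask]

    # independent diagnostic: 50% crossing of the reference stop-side edge,
    # measured with the same narrow band as the trace edges
    narrow = extract_profile(reference, band_halfwidth=2)
    narrow_attn, _ = _attenuation(narrow)
    level = 0.5 * float(narrow_attn.max())
    above = np.flatnonzero(narrow_attn >= level)
    if s > 0:
        ref_stop_crossing = _cross_right(
            narrow_attn, narrow.positions, int(above[-1]), level, reference.pixel_pitch
        )
    else:
        ref_stop_crossing = _cross_left(
            narrow_attn, narrow.positions, int(above[0]), level, reference.pixel_pitch
        )

    def objective(d_iso_mm: float) -> float:
        center = ref_det.center + s * d_iso_mm * mag
        u = s * (x_win - center)
        template = np.where(
            u <= 0.0, 1.0, np.interp(u, u_sorted, ref_sorted, right=0.0)
        )
        resid = trace_win - template
        return float(resid @ resid)

    info = {
        "p_ref": ref_det.center,
        "ref_fwhm": ref_det.fwhm,
        "lead_edge": lead,
        "stop_edge": stop,
        "ref_stop_crossing": ref_stop_crossing,
        "window_mm": (float(x_win.min()), float(x_win.max())) if x_win.size else None,
    }
    return objective, info


def beam_off_delay(
    reference: PortalImage,
    trace: PortalImage,
    geometry: BeamGeometry,
    velocity: float,
    direction: Direction = "descending",
    search: tuple[float, float] = DEFAULT_SEARCH_MM,
    repeat_index: int = 0,
    beam_mode: str = "",
) -> DelayMeasurement:
    """Beam-off delay via stop-edge template matching on the blur trace.

    A coarse grid (0.25 px steps over ``search``, mm at the isocenter
    plane) is refined to 0.05 px around the minimum.  A stop-edge
    50%-crossing estimate is compared as a diagnostic; disagreement beyond
    2 px emits a :class:`QualityWarning`.
    """
    lo, hi = search
    if not hi > lo:
        raise InvalidInputError(f"empty search range {search}")
    objective, info = beam_off_objective(reference, trace, geometry, direction)
    mag = geometry.magnification
    pitch = geometry.pixel_pitch
    coarse = COARSE_STEP_PX * pitch / mag
    fine = FINE_STEP_PX * pitch / mag

    grid = np.arange(lo, hi + coarse / 2, coarse)
    values = np.array([objective(d) for d in grid])
    i = int(np.argmin(values))
    if i == len(grid) - 1:
        raise SearchRangeError(
            f"matching objective still decreasing at the search limit {hi} mm"
        )
    f_lo = max(lo, grid[i] - 1.5 * coarse)
    f_hi = min(hi, grid[i] + 1.5 * coarse)
    fine_grid = np.arange(f_lo, f_hi + fine / 2, fine)
    d_star = float(fine_grid[np.argmin([objective(d) for d in fine_grid])])

    s = direction_sign(direction)
    d_edge = s * (info["stop_edge"] - info["ref_stop_crossing"]) / mag
    if abs(d_edge - d_star) * mag / pitch > 2.0:
        warnings.warn(
            f"edge-based estimate ({d_edge:.2f} mm) and matched displacement "
            f"({d_star:.2f} mm) disagree by more than 2 px",
            QualityWarning,
            stacklevel=2,
        )
    return _measurement(d_star, velocity, "beam_off", repeat_index, beam_mode)
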