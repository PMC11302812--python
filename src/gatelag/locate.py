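"""Sub-pixel localization of the metal ball and of blur-trace edges.

All detection works on a 1-D intensity profile taken along the motion
axis: pixel rows (transverse to the motion) are averaged over a band
centered on the ball, and the ball's attenuation (background minus
intensity) is analyzed.  The ball center is the attenuation-weighted
centroid of the contiguous region above 50% of the attenuation depth,
extended by a small margin so the antialiased edge tails contribute;
trace edges are the 50%-of-plateau crossings found by linear
interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    AmbiguousDetectionError,
    DegenerateTraceWarning,
    GeometryError,
    NoBallFoundError,
)
from .images import PortalImage
from .motion import Direction, direction_sign

HALF_DEPTH_THRESHOLD = 0.5  # fraction of attenuation depth defining the ball region
CENTROID_MARGIN_PX = 3  # edge-tail pixels included around the 50% region
_MIN_SNR = 6.0  # detection requires depth > _MIN_SNR * profile noise sigma


@dataclass(frozen=True)
class Profile:
    """A motion-axis intensity profile (band mean transverse to motion)."""

    positions: np.ndarray  # mm at detector plane, origin at image center
    intensities: np.ndarray  # counts
    band_halfwidth: int  # pixels
    center_row: int  # transverse index the band was centered on


@dataclass(frozen=True)
class BallDetection:
    """Sub-pixel ball location.

    ``center`` is in mm at the detector plane (origin at image center);
    ``center_px`` is the fractional pixel index along the motion axis.
    """

    center: float
    center_px: float
    depth: float
    fwhm: float
    quality: float


def _transverse_center(oriented: np.ndarray) -> int:
    """Row index of the ball: global minimum of the transverse row means.

    A featureless image (all row means equal) falls back to the middle row.
    """
    row_means = oriented.mean(axis=1)
    if np.ptp(row_means) == 0:
        return oriented.shape[0] // 2
    return int(np.argmin(row_means))


def estimate_ball_radius_px(image: PortalImage) -> float:
    """Half the transverse extent of the attenuation footprint, in pixels."""
    px = image.oriented()
    row_means = px.mean(axis=1)
    attn = np.median(row_means) - row_means
    peak = attn.max()
    if peak <= 0:
        return 1.0
    count = int(np.count_nonzero(attn >= 0.5 * peak))
    return max(count / 2.0, 1.0)


def _auto_band(image: PortalImage) -> int:
    # default transverse band: roughly the ball radius in pixels
    return max(int(round(estimate_ball_radius_px(image))) - 1, 1)


def extract_profile(
    image: PortalImage,
    band_halfwidth: int | None = None,
    center_row: int | None = None,
) -> Profile:
    """Band-averaged intensity profile along the motion axis.

    The band is centered on the ball's transverse coordinate (the row with
    the global minimum mean) and spans ``2 * band_halfwidth + 1`` rows.
    """
    px = image.oriented()
    if center_row is None:
        center_row = _transverse_center(px)
    if band_halfwidth is None:
        band_halfwidth = _auto_band(image)
    lo = center_row - band_halfwidth
    hi = center_row + band_halfwidth
    if lo < 0 or hi >= px.shape[0]:
        raise GeometryError(
            f"band rows [{lo}, {hi}] fall outside the image (nrows={px.shape[0]})"
        )
    intensities = px[lo : hi + 1].mean(axis=0)
    return Profile(
        positions=image.positions_mm(),
        intensities=intensities,
        band_halfwidth=int(band_halfwidth),
        center_row=int(center_row),
    )


def _attenuation(profile: Profile) -> tuple[np.ndarray, float]:
    background = float(np.median(profile.intensities))
    return background - profile.intensities, background


def _noise_sigma(attn: np.ndarray) -> float:
    # robust sigma via MAD; the ball occupies a small fraction of the profile
    return 1.4826 * float(np.median(np.abs(attn - np.median(attn))))


def _contiguous_runs(indices: np.ndarray) -> list[np.ndarray]:
    if indices.size == 0:
        return []
    breaks = np.where(np.diff(indices) > 1)[0]
    return np.split(indices, breaks + 1)


def _cross_left(attn: np.ndarray, positions: np.ndarray, i: int, level: float, pitch: float) -> float:
    """Interpolated crossing position left of in-region index ``i``."""
    if i == 0 or attn[i - 1] == attn[i]:
        return float(positions[i])
    frac = (level - attn[i - 1]) / (attn[i] - attn[i - 1])
    return float(positions[i - 1] + frac * pitch)


def _cross_right(attn: np.ndarray, positions: np.ndarray, i: int, level: float, pitch: float) -> float:
    if i == attn.size - 1 or attn[i + 1] == attn[i]:
        return float(positions[i])
    frac = (attn[i] - level) / (attn[i] - attn[i + 1])
    return float(positions[i] + frac * pitch)


def locate_ball_center(
    image: PortalImage, band_halfwidth: int | None = None
) -> BallDetection:
    """Locate a single ball footprint with sub-pixel precision.

    Raises
    ------
    NoBallFoundError
        If no attenuation region rises clearly above the noise.
    AmbiguousDetectionError
        If more than one disjoint region exceeds the 50%-depth threshold.
    """
    profile = extract_profile(image, band_halfwidth)
    attn, _ = _attenuation(profile)
    sigma = _noise_sigma(attn)
    depth = float(attn.max())
    if depth <= 0 or depth < _MIN_SNR * sigma:
        raise NoBallFoundError(
            f"no ball: attenuation depth {depth:.3g} vs noise sigma {sigma:.3g}"
        )
    threshold = HALF_DEPTH_THRESHOLD * depth
    runs = _contiguous_runs(np.flatnonzero(attn >= threshold))
    peak = int(np.argmax(attn))
    main = next(run for run in runs if run[0] <= peak <= run[-1])
    if len(runs) > 1:
        raise AmbiguousDetectionError(
            f"{len(runs)} disjoint regions exceed the detection threshold"
        )
    # Attenuation-weighted centroid over the 50% region extended by
    # CENTROID_MARGIN_PX pixels on each side.  The margin captures the
    # antialiased edge tails, whose weights fall smoothly to zero, so the
    # centroid is free of the sub-pixel jitter a hard pixel-in/pixel-out
    # cut at the 50% boundary would cause.
    pitch = image.pixel_pitch
    lo = max(int(main[0]) - CENTROID_MARGIN_PX, 0)
    hi = min(int(main[-1]) + CENTROID_MARGIN_PX, attn.size - 1)
    w = np.clip(attn[lo : hi + 1], 0.0, None)
    x = profile.positions[lo : hi + 1]
    center = float(np.sum(w * x) / np.sum(w))
    center_px = image.mm_to_px(center)
    left = _cross_left(attn, profile.positions, int(main[0]), threshold, pitch)
    right = _cross_right(attn, profile.positions, int(main[-1]), threshold, pitch)
    # quality compares the depth against the raw per-pixel image noise
    pixel_sigma = 1.4826 * float(
        np.median(np.abs(image.pixels - np.median(image.pixels)))
    )
    quality = 1.0 if pixel_sigma == 0 else min(1.0, depth / (50.0 * pixel_sigma))
    return BallDetection(
        center=center,
        center_px=center_px,
        depth=depth,
        fwhm=right - left,
        quality=quality,
    )


def locate_trace_edges(
    image: PortalImage,
    direction: Direction = "descending",
    band_halfwidth: int = 2,
) -> tuple[float, float]:
    """Locate the lead and stop edges of a motion-blur trace.

    Edges are the outermost 50%-of-plateau crossings of the attenuation
    profile, linearly interpolated between bracketing pixels.  A narrow
    transverse band (default halfwidth 2 px) keeps the 50% crossing at the
    geometric disk boundary.  ``stop_edge`` is the edge in the direction
    of motion.

    Returns
    -------
    (lead_edge, stop_edge) in mm at the detector plane.
    """
    profile = extract_profile(image, band_halfwidth)
    attn, _ = _attenuation(profile)
    depth = float(attn.max())
    if depth <= 0:
        raise NoBallFoundError("no trace: flat profile")
    plateau = float(np.median(attn[attn >= 0.7 * depth]))
    level = HALF_DEPTH_THRESHOLD * plateau
    above = np.flatnonzero(attn >= level)
    if above.size == 0:
        raise NoBallFoundError("no trace: nothing above the 50% plateau level")
    pitch = image.pixel_pitch
    left = _cross_left(attn, profile.positions, int(above[0]), level, pitch)
    right = _cross_right(attn, profile.positions, int(above[-1]), level, pitch)
    extent = right - left
    radius_mm = estimate_ball_radius_px(image) * pitch
    travel = extent - 2.0 * radius_mm
    if travel < 3.0 * radius_mm:
        warnings.warn(
            f"trace travel ({travel:.1f} mm) is under 3 ball radii; "
            "edges may lack a clear plateau",
            DegenerateTraceWarning,
            stacklevel=2,
        )
    if direction_sign(direction) > 0:
        return left, right
    return right, left
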