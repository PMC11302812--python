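"""Projection geometry of the linac / EPID setup.

The phantom moves at the isocenter plane (source-to-axis distance SAD);
the flat-panel imager sits further from the source (source-to-imager
distance SID).  By similar triangles, a displacement ``dx`` at the
isocenter plane projects to ``dx * sid / sad`` at the detector plane, so
detector-plane measurements divide by the magnification ``M = sid / sad``
to recover physical phantom displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError


@dataclass(frozen=True)
class BeamGeometry:
    """Projection parameters of the imaging chain.

    Parameters
    ----------
    sad : float
        Source-to-axis distance in mm (isocenter plane).
    sid : float
        Source-to-imager distance in mm.
    pixel_pitch : float
        Detector pixel pitch in mm per pixel.
    image_shape : tuple of int
        (rows, cols) of the portal image.
    """

    sad: float = 1000.0
    sid: float = 1600.0
    pixel_pitch: float = 0.34
    image_shape: tuple[int, int] = (192, 512)

    def __post_init__(self) -> None:
        if not self.sad > 0:
            raise InvalidInputError(f"sad must be positive, got {self.sad}")
        if self.sid < self.sad:
            raise InvalidInputError(
                f"sid ({self.sid}) must be >= sad ({self.sad})"
            )
        if not self.pixel_pitch > 0:
            raise InvalidInputError(
                f"pixel_pitch must be positive, got {self.pixel_pitch}"
            )
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise InvalidInputError(f"bad image_shape {self.image_shape}")

    @property
    def magnification(self) -> float:
        """Projective magnification SID / SAD (>= 1)."""
        return self.sid / self.sad

    def iso_to_detector(self, x_iso_mm: float) -> float:
        """Project an isocenter-plane position/displacement onto the detector."""
        return x_iso_mm * self.magnification

    def detector_to_iso(self, x_det_mm: float) -> float:
        """Back-project a detector-plane position/displacement to the isocenter."""
        return x_det_mm / self.magnification
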