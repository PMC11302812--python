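"""Portal image container and file I/O (PNG/TIFF/DICOM secondary capture)."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

# Positions along the motion axis are measured in mm at the detector plane,
# origin at the image center, increasing with pixel index.

_UID_ROOT = "1.2.826.0.1.3680043.10.1437"  # generated org root for this package


@dataclass
class PortalImage:
    """A 2-D portal image with its physical pixel pitch.

    Attributes
    ----------
    pixels : ndarray
        2-D array of detector counts (finite, >= 0).
    pixel_pitch : float
        mm per pixel at the detector plane.
    motion_axis : str
        ``"cols"`` if the phantom moves along the column axis (default),
        ``"rows"`` otherwise.
    """

    pixels: np.ndarray
    pixel_pitch: float
    motion_axis: str = "cols"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidInputError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("pixel values must be finite")
        if np.any(self.pixels < 0):
            raise InvalidInputError("pixel values must be non-negative")
        if not self.pixel_pitch > 0:
            raise InvalidInputError("pixel_pitch must be positive")
        if self.motion_axis not in ("rows", "cols"):
            raise InvalidInputError(f"bad motion_axis {self.motion_axis!r}")

    @property
    def motion_n(self) -> int:
        """Number of pixels along the motion axis."""
        return self.pixels.shape[1] if self.motion_axis == "cols" else self.pixels.shape[0]

    def oriented(self) -> np.ndarray:
        """Pixels with the motion axis as axis 1 (columns)."""
        return self.pixels if self.motion_axis == "cols" else self.pixels.T

    def positions_mm(self) -> np.ndarray:
        """Motion-axis pixel-center positions in mm from the image center."""
        n = self.motion_n
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    def px_to_mm(self, px: float) -> float:
        return (px - (self.motion_n - 1) / 2.0) * self.pixel_pitch

    def mm_to_px(self, mm: float) -> float:
        return mm / self.pixel_pitch + (self.motion_n - 1) / 2.0


def _to_uint16(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)


def write_image(image: PortalImage, path: str | Path) -> Path:
    """Write a portal image as 16-bit PNG, TIFF, or DICOM secondary capture.

    The format follows the file suffix (.png, .tif/.tiff, .dcm).  PNG and
    TIFF do not carry the pixel pitch; readers must supply it.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    arr = _to_uint16(image.pixels)
    if suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif suffix == ".dcm":
        _write_dicom(arr, image.pixel_pitch, path)
    else:
        raise InvalidInputError(f"unsupported image format: {suffix!r}")
    return path


def _write_dicom(arr: np.ndarray, pixel_pitch: float, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    # deterministic SOP instance UID derived from the pixel payload
    digest = int.from_bytes(hashlib.sha1(arr.tobytes()).digest()[:8], "big")
    sop_uid = f"{_UID_ROOT}.{digest}"

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "OT"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.ImagePlanePixelSpacing = [pixel_pitch, pixel_pitch]
    ds.PixelData = np.ascontiguousarray(arr).tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def read_image(
    path: str | Path,
    pixel_pitch: float | None = None,
    motion_axis: str = "cols",
) -> PortalImage:
    """Read a portal image from PNG, TIFF, or DICOM.

    For DICOM, the pixel pitch is taken from ImagePlanePixelSpacing /
    PixelSpacing when present; an explicit ``pixel_pitch`` overrides it.
    For PNG and TIFF, ``pixel_pitch`` is required.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcm":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        if pixel_pitch is None:
            spacing = getattr(ds, "ImagePlanePixelSpacing", None) or getattr(
                ds, "PixelSpacing", None
            )
            if spacing is None:
                raise InvalidInputError(
                    f"{path}: no pixel spacing in DICOM; pass pixel_pitch"
                )
            pixel_pitch = float(spacing[1])
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    else:
        raise InvalidInputError(f"unsupported image format: {suffix!r}")
    if pixel_pitch is None:
        raise InvalidInputError(f"{path}: pixel_pitch required for {suffix} images")
    return PortalImage(arr, pixel_pitch, motion_axis, meta={"path": str(path)})
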