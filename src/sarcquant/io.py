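"""Image I/O and pixel calibration.

Every downstream measurement is expressed in microns, so a single isotropic
pixel calibration (µm/px) is mandatory configuration; it is never inferred
from TIFF tags (tag dialects are unreliable).

Coordinate convention used throughout the package: images are indexed 0-based
as (row, col) with pixel centers at integer coordinates. The geometric frame
is right-handed with +x along columns and +y along *negative* rows, so angle
conventions match standard mathematics (counterclockwise positive, 0° along
+x). Physical coordinates of pixel (r, c) are
``(x, y) = (c * µm_per_px, -r * µm_per_px)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "PixelCalibration",
    "px_to_um",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "pixel_xy",
]


@dataclass(frozen=True)
class PixelCalibration:
    """Isotropic pixel size.

    Parameters
    ----------
    microns_per_pixel : float
        Physical edge length of a pixel in µm. Must be strictly positive.
        Anisotropic calibrations are not supported; supply a pre-resampled
        image instead.
    """

    microns_per_pixel: float

    def __post_init__(self) -> None:
        mpp = self.microns_per_pixel
        if not np.isfinite(mpp) or mpp <= 0:
            raise ValueError(
                f"microns_per_pixel must be finite and > 0, got {mpp!r}"
            )


def px_to_um(length_px: float, cal: PixelCalibration) -> float:
    """Convert a pixel length to µm. Raises on negative input."""
    if length_px < 0:
        raise ValueError(f"length_px must be >= 0, got {length_px!r}")
    return float(length_px) * cal.microns_per_pixel


def pixel_xy(rows: np.ndarray, cols: np.ndarray, cal: PixelCalibration):
    """Map (row, col) pixel indices to physical (x, y) in µm.

    +x runs along columns, +y along negative rows (right-handed frame).
    """
    mpp = cal.microns_per_pixel
    return np.asarray(cols, dtype=float) * mpp, -np.asarray(rows, dtype=float) * mpp


def read_image(path) -> np.ndarray:
    """Read a single-channel 8- or 16-bit TIFF as a 2-D array.

    One stain per file: multi-channel/RGB input is rejected rather than
    silently collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"single-channel required: {path.name} has shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"8- or 16-bit integer TIFF required, got dtype {arr.dtype}"
        )
    return arr


def write_image(path, pixels: np.ndarray) -> None:
    """Write a 2-D integer array as a single-channel TIFF."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"2-D array required, got shape {pixels.shape}")
    tifffile.imwrite(str(path), pixels)


def read_mask(path) -> np.ndarray:
    """Read a binary mask TIFF; any nonzero pixel is foreground.

    Masks are stored on disk as 8-bit {0, 255} and normalized to boolean
    on read.
    """
    arr = read_image(path)
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit {0, 255} TIFF."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"2-D mask required, got shape {mask.shape}")
    write_image(path, (mask > 0).astype(np.uint8) * 255)
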