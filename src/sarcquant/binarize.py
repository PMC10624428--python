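"""Reference binarization and mask cleanup.

The quantifier consumes only binary masks and is agnostic to how they were
produced. This module provides the classical Otsu reference binarizer plus a
pass-through for externally produced binaries (e.g., from a deep-learning
segmenter), so any mask source can be dropped in.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import PixelCalibration, read_mask

__all__ = ["otsu_binarize", "clean_mask", "load_external_mask"]

# one global convention: foreground components are 8-connected
CONNECTIVITY_STRUCT = np.ones((3, 3), dtype=bool)


def otsu_binarize(img: np.ndarray) -> np.ndarray:
    """Threshold a grayscale image with Otsu's criterion.

    The threshold t maximizes the between-class variance of the intensity
    histogram; a pixel is foreground iff its intensity is strictly greater
    than t (ties go to background, deterministically).

    Raises
    ------
    ValueError
        If the image is constant (no threshold separates two classes).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"2-D image required, got shape {img.shape}")
    if img.min() == img.max():
        raise ValueError("constant image: Otsu threshold undefined")
    t = threshold_otsu(img)
    return img > t


def clean_mask(
    mask: np.ndarray, min_object_area: float, cal: PixelCalibration
) -> np.ndarray:
    """Drop 8-connected foreground components smaller than ``min_object_area`` µm².

    ``min_object_area = 0`` disables the filter. Idempotent.
    """
    if min_object_area < 0:
        raise ValueError("min_object_area must be >= 0")
    mask = np.asarray(mask) > 0
    if min_object_area == 0:
        return mask.copy()
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_STRUCT)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    area_um2 = sizes * cal.microns_per_pixel**2
    keep = area_um2 >= min_object_area  # strict <: components at the bound stay
    keep[0] = False
    return keep[labels]


def load_external_mask(path, expected_shape=None) -> np.ndarray:
    """Load an externally produced binary mask, validating its shape."""
    mask = read_mask(path)
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValueError(
            f"external mask shape {mask.shape} does not match expected "
            f"{tuple(expected_shape)}"
        )
    return mask
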