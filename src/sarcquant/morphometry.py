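"""Per-structure morphometry of binary masks.

Connected components of a mask (8-connected, the package-wide convention)
become :class:`Structure` records carrying the geometry every classifier and
chaining rule downstream consumes: centroid, long-axis (max-Feret) length,
principal-axis orientation, area, aspect ratio, and hole topology.

Length thresholds separating puncta from lines are the tool-defining
parameters: an α-actinin-2 structure longer than 1.4 µm is a potential
Z-Line (anything else a potential Z-Body), a titin line must exceed 1.7 µm
to be doublet-eligible, and a myomesin M-Line must exceed 1.4 µm. All of
them, like every other rule parameter, are user-settable via
:class:`QuantParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .io import PixelCalibration, pixel_xy

__all__ = [
    "QuantParams",
    "Structure",
    "label_structures",
    "measure_length",
    "measure_orientation",
    "classify_structure",
]

Stain = Literal["actinin", "titin", "myomesin"]

CONNECTIVITY_STRUCT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class QuantParams:
    """All tunable rule parameters, with the tool's default values.

    Lengths are µm, angles degrees, counts structure counts. Defaults encode
    the quantification rules: Z-Line length > 1.4 µm, titin line > 1.7 µm,
    M-Line > 1.4 µm; chaining requires centroid spacing < 3 µm and long-axis
    angle difference within 30°; a myofibril needs ≥ 4 Z-Lines (or titin
    doublets) but only ≥ 3 M-Lines; MSF grouping requires Z-Body rows
    < 3 µm apart and within 30° of the local cell edge.

    ``angle_tol_deg`` and ``dist_tol_um`` are numerical guards applied at
    threshold comparisons so that structures rendered exactly at a threshold
    are not flipped across it by sub-pixel rasterization noise; both are far
    below any biologically meaningful difference.
    """

    zline_min_len: float = 1.4
    titin_line_min_len: float = 1.7
    mline_min_len: float = 1.4
    max_link_gap: float = 3.0
    max_link_angle: float = 30.0
    min_zlines_per_myofibril: int = 4
    min_mlines_per_myofibril: int = 3
    min_doublets_per_myofibril: int = 4
    msf_max_gap: float = 3.0
    msf_edge_angle: float = 30.0
    min_bodies_per_msf: int = 3
    doublet_pair_max_gap: float = 1.0
    doublet_pair_max_angle: float = 15.0
    lp_cap: float = 500.0
    lateral_stack_angle: float = 45.0
    angle_tol_deg: float = 0.05
    dist_tol_um: float = 0.005

    def __post_init__(self) -> None:
        for name in (
            "zline_min_len",
            "titin_line_min_len",
            "mline_min_len",
            "max_link_gap",
            "msf_max_gap",
            "doublet_pair_max_gap",
            "lp_cap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "max_link_angle",
            "msf_edge_angle",
            "doublet_pair_max_angle",
            "lateral_stack_angle",
        ):
            v = getattr(self, name)
            if not (0 < v <= 90):
                raise ValueError(f"{name} must be in (0, 90], got {v}")
        for name in (
            "min_zlines_per_myofibril",
            "min_mlines_per_myofibril",
            "min_doublets_per_myofibril",
            "min_bodies_per_msf",
        ):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.angle_tol_deg < 0 or self.dist_tol_um < 0:
            raise ValueError("numerical tolerances must be >= 0")

    def replace(self, **overrides) -> "QuantParams":
        kw = {f.name: getattr(self, f.name) for f in fields(self)}
        kw.update(overrides)
        return QuantParams(**kw)


@dataclass
class Structure:
    """One labeled connected component of a binary mask."""

    id: int
    centroid: tuple[float, float]  # (x, y) µm
    length_um: float  # max-Feret diameter
    orientation_deg: float  # [0, 180), degrees from +x
    orientation_degenerate: bool
    area_um2: float
    aspect_ratio: float
    has_hole: bool
    filled_area_um2: float
    pixel_count: int
    # (row, col) indices of member pixels, kept for topology-aware
    # downstream measurements (ring moments)
    pixels: np.ndarray = field(repr=False, default=None)


def measure_length(pixel_rc: np.ndarray, cal: PixelCalibration) -> float:
    """Max-Feret diameter of a pixel set: the maximum pairwise distance
    between pixel centers, in µm. A single pixel has length 0.

    For large sets the maximum is attained on the convex hull of the pixel
    centers, which keeps this O(h²) instead of O(n²).
    """
    pts = np.asarray(pixel_rc, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("non-empty (n, 2) pixel set required")
    if pts.shape[0] == 1:
        return 0.0
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] > 3:
        try:
            hull = ConvexHull(uniq)
            uniq = uniq[hull.vertices]
        except Exception:
            # degenerate (collinear) sets: fall back to all points
            pass
    return float(pdist(uniq).max()) * cal.microns_per_pixel


def _central_moments(pixel_rc: np.ndarray):
    """Second central moments of pixel centers in the (x, y) frame."""
    rr = pixel_rc[:, 0].astype(float)
    cc = pixel_rc[:, 1].astype(float)
    x = cc - cc.mean()
    y = -(rr - rr.mean())
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    return mu20, mu02, mu11


def measure_orientation(pixel_rc: np.ndarray) -> tuple[float, bool]:
    """Principal-axis angle of a pixel set, degrees in [0, 180) from +x.

    Returns ``(angle, degenerate)``: a single pixel (or an isotropic set with
    no preferred axis) reports angle 0 with the degeneracy flag set.
    """
    pts = np.asarray(pixel_rc)
    if pts.shape[0] < 2:
        return 0.0, True
    mu20, mu02, mu11 = _central_moments(pts)
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        return 0.0, True
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return float(np.rad2deg(theta) % 180.0), False


def _aspect_ratio(pixel_rc: np.ndarray) -> float:
    """Major/minor axis ratio from the moment ellipse of a pixel set.

    Each pixel contributes its unit-square extent (variance 1/12 per axis),
    so a single pixel is isotropic (ratio 1) rather than degenerate.
    """
    mu20, mu02, mu11 = _central_moments(np.asarray(pixel_rc))
    mu20 += 1.0 / 12.0
    mu02 += 1.0 / 12.0
    common = np.sqrt(max((mu20 - mu02) ** 2 + 4.0 * mu11**2, 0.0))
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    if lam2 <= 0:
        return float("inf")
    return float(np.sqrt(lam1 / lam2))


def label_structures(
    mask: np.ndarray, cal: PixelCalibration
) -> list[Structure]:
    """Label 8-connected foreground components and measure each one.

    Ids are assigned deterministically in raster order of each component's
    first (top-most, then left-most) pixel, starting at 1. An empty mask
    yields an empty list.
    """
    mask = np.asarray(mask) > 0
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_STRUCT)
    out: list[Structure] = []
    if n == 0:
        return out
    mpp = cal.microns_per_pixel
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        rr, cc = np.nonzero(sub)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        pix = np.column_stack([rr, cc])
        count = pix.shape[0]
        x, y = pixel_xy(rr, cc, cal)
        centroid = (float(x.mean()), float(y.mean()))
        length = measure_length(pix, cal)
        orient, degen = measure_orientation(pix)
        filled = ndimage.binary_fill_holes(sub)
        filled_count = int(filled.sum())
        # a hole must exceed one pixel's area to count (threshold-free
        # topology flagging would otherwise fire on single-pixel dropouts)
        has_hole = (filled_count - count) > 1
        out.append(
            Structure(
                id=lab,
                centroid=centroid,
                length_um=length,
                orientation_deg=orient,
                orientation_degenerate=degen,
                area_um2=count * mpp**2,
                aspect_ratio=_aspect_ratio(pix),
                has_hole=has_hole,
                filled_area_um2=filled_count * mpp**2,
                pixel_count=count,
                pixels=pix,
            )
        )
    return out


def classify_structure(
    s: Structure, params: QuantParams, stain: Stain
) -> str:
    """Classify a structure as ``candidate_line``, ``candidate_body`` or
    (titin only) ``candidate_ring``.

    Rings take precedence for titin: any hole-bearing titin structure is a
    precursor-ring candidate regardless of length. Otherwise the call is a
    strict length comparison against the stain's threshold: > 1.4 µm for
    α-actinin-2 (Z-Line vs Z-Body), > 1.7 µm for titin lines, > 1.4 µm for
    myomesin M-Lines. A structure exactly at the threshold is a body.
    """
    if stain == "titin" and s.has_hole:
        return "candidate_ring"
    thr = {
        "actinin": params.zline_min_len,
        "titin": params.titin_line_min_len,
        "myomesin": params.mline_min_len,
    }[stain]
    if s.length_um > thr + params.dist_tol_um:
        return "candidate_line"
    return "candidate_body"
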