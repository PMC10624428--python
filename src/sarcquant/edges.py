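"""Cell-outline extraction and edge-relative geometry.

Myofibril orientation is reported relative to the nearest cell edge: the
edge segment found perpendicular to the myofibril long axis serves as the
reference, and the output is the folded difference between the myofibril
axis angle and that edge tangent (0° = parallel to the edge, 90° =
perpendicular). The outline comes from a co-stain mask (e.g., actin or
non-muscle myosin) because the sarcomeric stains themselves do not label
the cell edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.polygon import orient as shapely_orient
from skimage import measure as skmeasure

from .io import PixelCalibration

__all__ = [
    "CellOutline",
    "extract_outline",
    "nearest_edge_reference",
    "min_distance_to_edge",
    "relative_angle",
]

CONNECTIVITY_STRUCT = np.ones((3, 3), dtype=bool)


def relative_angle(a_deg: float, b_deg: float) -> float:
    """Fold the difference of two axial angles (each in [0, 180)) into
    [0, 90]: axes have no direction, so 175° vs 5° differ by 10°, not 170°.
    """
    d = abs(float(a_deg) - float(b_deg)) % 180.0
    return 180.0 - d if d > 90.0 else d


def _segment_angle(p0, p1) -> float:
    """Axial angle of a segment, degrees in [0, 180) from +x."""
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    return float(np.rad2deg(np.arctan2(dy, dx)) % 180.0)


@dataclass
class CellOutline:
    """Closed, simple polygon of the cell boundary in µm coordinates.

    Tangent angles are evaluated on the simplified polygon's segments
    (one-sided convention at vertices: a boundary point gets the tangent of
    the segment it lies on, vertices the following segment).
    """

    vertices: np.ndarray  # (n, 2) closed ring, counterclockwise, µm

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape[0] < 4 or not np.allclose(v[0], v[-1]):
            raise ValueError("vertices must form a closed ring")
        self.vertices = v
        self.polygon = Polygon(v)
        if not self.polygon.is_valid:
            self.polygon = self.polygon.buffer(0)

    @property
    def arc_length(self) -> float:
        return float(self.polygon.exterior.length)

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)

    def segments(self):
        v = np.asarray(self.polygon.exterior.coords)
        return [(v[i], v[i + 1]) for i in range(len(v) - 1)]

    def contains(self, point) -> bool:
        p = Point(point)
        return bool(self.polygon.covers(p))

    def tangent_at_point(self, point) -> float:
        """Tangent angle ([0, 180)) of the boundary segment nearest to a
        point that lies on (or numerically near) the boundary."""
        p = Point(point)
        best, best_d = None, np.inf
        for p0, p1 in self.segments():
            d = LineString([p0, p1]).distance(p)
            if d < best_d:
                best, best_d = (p0, p1), d
        return _segment_angle(*best)


def extract_outline(cell_mask: np.ndarray, cal: PixelCalibration) -> CellOutline:
    """Trace the boundary polygon of the largest foreground component.

    The component is hole-filled first (the outline describes the cell
    silhouette, not internal stain gaps), traced with marching squares at
    the 0.5 level, oriented counterclockwise in the (x, +y-up) frame, and
    simplified with a 0.5 px tolerance. Cells clipped by the image border
    get boundary segments that follow the border.
    """
    mask = np.asarray(cell_mask) > 0
    if not mask.any():
        raise ValueError("empty cell mask: no outline to extract")
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_STRUCT)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
    mask = ndimage.binary_fill_holes(mask)
    padded = np.pad(mask, 1).astype(float)
    contours = skmeasure.find_contours(padded, 0.5)
    contour = max(contours, key=lambda c: c.shape[0])
    rr = contour[:, 0] - 1.0
    cc = contour[:, 1] - 1.0
    mpp = cal.microns_per_pixel
    xy = np.column_stack([cc * mpp, -rr * mpp])
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    # tolerance just under the half-pixel corner-cut depth: collinear
    # contour points collapse, but corner vertices survive, so long straight
    # edges keep their exact axis-aligned tangent
    poly = poly.simplify(0.4 * mpp, preserve_topology=True)
    poly = shapely_orient(poly, sign=1.0)  # counterclockwise
    return CellOutline(np.asarray(poly.exterior.coords))


def min_distance_to_edge(outline: CellOutline, point) -> float:
    """Minimum Euclidean distance (µm) from an interior point to the
    outline polygon."""
    if not outline.contains(point):
        raise ValueError(f"point {point} lies outside the cell outline")
    return float(outline.polygon.exterior.distance(Point(point)))


def nearest_edge_reference(
    outline: CellOutline, point, axis_deg: float
) -> tuple[tuple[float, float], float, float]:
    """Edge reference for an axis through an interior point.

    Casts rays from ``point`` in both directions perpendicular to
    ``axis_deg`` and takes the nearer intersection with the outline: the
    edge "parallel" to a myofibril is the one met along its normal. Returns
    ``(edge_point, edge_tangent_deg, distance_um)``.
    """
    if not outline.contains(point):
        raise ValueError(f"point {point} lies outside the cell outline")
    px, py = float(point[0]), float(point[1])
    theta = np.deg2rad(float(axis_deg) + 90.0)
    d = np.array([np.cos(theta), np.sin(theta)])
    # ray length comfortably beyond any cell: bounding-box diagonal
    minx, miny, maxx, maxy = outline.polygon.bounds
    span = float(np.hypot(maxx - minx, maxy - miny)) + 1.0

    best = None  # (distance, point)
    for sign in (+1.0, -1.0):
        ray = LineString(
            [(px, py), (px + sign * span * d[0], py + sign * span * d[1])]
        )
        inter = ray.intersection(outline.polygon.exterior)
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            pts = (
                [g] if g.geom_type == "Point" else [Point(c) for c in g.coords]
            )
            for q in pts:
                dist = float(np.hypot(q.x - px, q.y - py))
                if best is None or dist < best[0]:
                    best = (dist, (float(q.x), float(q.y)))
    if best is None:
        raise ValueError("no intersection with the outline (malformed polygon)")
    dist, epoint = best
    tangent = outline.tangent_at_point(epoint)
    return epoint, tangent, dist
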