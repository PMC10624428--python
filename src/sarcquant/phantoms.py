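"""Synthetic phantoms with known ground truth.

Every detector in the package is exercised by programmatically rendered
binary images: single bars (threshold sweeps), Z-Line ladders (myofibrils),
Z-Body rows (MSFs), titin doublet ladders, annular rings, and a
three-modality composite cell. Rasterization is anti-alias-free
pixel-center containment — a pixel belongs to an element iff its center
does — which is parameter-free and bit-reproducible across platforms.

Phantom coordinates live in the package's physical frame: x increases along
columns, y along negative rows, so an image of shape (H, W) at calibration
``mpp`` spans x ∈ [0, (W−1)·mpp], y ∈ [−(H−1)·mpp, 0].

The module also provides a discrete 2-D worm-like-chain sampler used to
validate the persistence-length estimator against known stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .io import PixelCalibration

__all__ = [
    "Bar",
    "Disk",
    "RingElement",
    "ladder_bars",
    "body_row_disks",
    "PhantomSpec",
    "GroundTruth",
    "render",
    "render_cell_mask",
    "simulate_wlc_chain",
    "arc_points",
    "square_cell_vertices",
    "standard_suite",
    "composite_cell",
]


# ---------------------------------------------------------------- primitives


@dataclass(frozen=True)
class Bar:
    """Axis-angled solid rectangle (a Z-Line / titin line / M-Line)."""

    center: tuple[float, float]  # (x, y) µm
    length_um: float
    width_um: float
    angle_deg: float  # long-axis angle from +x


@dataclass(frozen=True)
class Disk:
    """Solid circle (a Z-Body)."""

    center: tuple[float, float]
    diameter_um: float


@dataclass(frozen=True)
class RingElement:
    """Elliptical annulus (a titin precursor ring). ``outer_axes_um`` are
    the full outer axes; the inner void has semi-axes smaller by
    ``thickness_um``."""

    center: tuple[float, float]
    outer_axes_um: tuple[float, float]
    thickness_um: float
    angle_deg: float = 0.0


def ladder_bars(
    n: int,
    center: tuple[float, float],
    bar_length_um: float,
    bar_width_um: float,
    bar_angle_deg: float,
    spacing_um: float,
    normal_deg: float | None = None,
) -> list[Bar]:
    """A ladder of ``n`` parallel bars whose centers advance by
    ``spacing_um`` along ``normal_deg`` (default: the bars' normal),
    centered as a group on ``center``."""
    if normal_deg is None:
        normal_deg = bar_angle_deg + 90.0
    t = np.deg2rad(normal_deg)
    d = np.array([np.cos(t), np.sin(t)])
    c0 = np.asarray(center, dtype=float) - d * spacing_um * (n - 1) / 2.0
    return [
        Bar(tuple(c0 + d * spacing_um * k), bar_length_um, bar_width_um, bar_angle_deg)
        for k in range(n)
    ]


def body_row_disks(
    n: int,
    center: tuple[float, float],
    diameter_um: float,
    spacing_um: float,
    angle_deg: float,
) -> list[Disk]:
    """A row of ``n`` disks advancing along ``angle_deg``, centered as a
    group on ``center``."""
    t = np.deg2rad(angle_deg)
    d = np.array([np.cos(t), np.sin(t)])
    c0 = np.asarray(center, dtype=float) - d * spacing_um * (n - 1) / 2.0
    return [Disk(tuple(c0 + d * spacing_um * k), diameter_um) for k in range(n)]


# ------------------------------------------------------------------- spec


@dataclass
class GroundTruth:
    """What the quantifier should find, by construction."""

    elements: dict = field(default_factory=dict)  # stain -> list of dicts
    expected: dict = field(default_factory=dict)  # metric name -> value


@dataclass
class PhantomSpec:
    shape_px: tuple[int, int]  # (rows, cols)
    cal: PixelCalibration
    elements: dict = field(default_factory=dict)  # stain -> list of primitives
    cell_vertices: np.ndarray | None = None  # closed polygon, µm
    seed: int = 0


def _grid(shape_px, cal):
    h, w = shape_px
    mpp = cal.microns_per_pixel
    x = np.arange(w, dtype=float) * mpp
    y = -np.arange(h, dtype=float) * mpp
    return np.meshgrid(x, y)  # X[r, c], Y[r, c]


# containment tolerance: pixel centers landing exactly on an element
# boundary are included regardless of float rounding, so nominal sizes
# rasterize to their intended pixel extent
_EPS = 1e-9


def _raster_bar(X, Y, bar: Bar):
    t = np.deg2rad(bar.angle_deg)
    dx = X - bar.center[0]
    dy = Y - bar.center[1]
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (np.abs(u) <= bar.length_um / 2.0 + _EPS) & (
        np.abs(v) <= bar.width_um / 2.0 + _EPS
    )


def _raster_disk(X, Y, disk: Disk):
    r = disk.diameter_um / 2.0
    return (X - disk.center[0]) ** 2 + (Y - disk.center[1]) ** 2 <= r**2 + _EPS


def _raster_ring(X, Y, ring: RingElement):
    t = np.deg2rad(ring.angle_deg)
    dx = X - ring.center[0]
    dy = Y - ring.center[1]
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    ao, bo = ring.outer_axes_um[0] / 2.0, ring.outer_axes_um[1] / 2.0
    ai, bi = ao - ring.thickness_um, bo - ring.thickness_um
    outer = (u / ao) ** 2 + (v / bo) ** 2 <= 1.0 + _EPS
    if ai <= 0 or bi <= 0:
        return outer
    inner = (u / ai) ** 2 + (v / bi) ** 2 < 1.0 - _EPS
    return outer & ~inner


_RASTERIZERS = {Bar: _raster_bar, Disk: _raster_disk, RingElement: _raster_ring}


def render_cell_mask(spec: PhantomSpec) -> np.ndarray | None:
    """Rasterize the cell polygon (pixel-center containment)."""
    if spec.cell_vertices is None:
        return None
    X, Y = _grid(spec.shape_px, spec.cal)
    poly = shapely.Polygon(np.asarray(spec.cell_vertices, dtype=float))
    return shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)


def render(spec: PhantomSpec) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    """Render one binary mask per stain plus the cell mask.

    Deterministic: the same spec always produces identical masks. Raises if
    an element's pixels would fall outside the image.
    """
    X, Y = _grid(spec.shape_px, spec.cal)
    masks: dict[str, np.ndarray] = {}
    h, w = spec.shape_px
    mpp = spec.cal.microns_per_pixel
    for stain, elems in spec.elements.items():
        m = np.zeros(spec.shape_px, dtype=bool)
        for el in elems:
            r = _RASTERIZERS[type(el)](X, Y, el)
            if not r.any():
                raise ValueError(f"{stain} element {el} renders no pixels")
            rr, cc = np.nonzero(r)
            if rr.min() == 0 or cc.min() == 0 or rr.max() == h - 1 or cc.max() == w - 1:
                raise ValueError(
                    f"{stain} element {el} touches the image border "
                    f"(image {h}x{w} px at {mpp} µm/px)"
                )
            m |= r
        masks[stain] = m
    return masks, render_cell_mask(spec)


# ------------------------------------------------------- reference shapes


def square_cell_vertices(x0: float, y_top: float, side: float) -> np.ndarray:
    """Closed square polygon with top-left corner (x0, y_top), sides
    axis-aligned, extending right and downward (toward negative y)."""
    return np.array(
        [
            [x0, y_top],
            [x0 + side, y_top],
            [x0 + side, y_top - side],
            [x0, y_top - side],
            [x0, y_top],
        ]
    )


def arc_points(radius_um: float, n: int, contour_um: float, center=(0.0, 0.0)):
    """``n`` points equally spaced along a circular arc of the given radius
    and arc length, starting at angle 0. Analytic reference for the
    persistence-length estimator."""
    s = np.linspace(0.0, contour_um, n)
    phi = s / radius_um
    return np.column_stack(
        [center[0] + radius_um * np.cos(phi), center[1] + radius_um * np.sin(phi)]
    )


def simulate_wlc_chain(
    lp_um: float, contour_um: float, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a discrete 2-D worm-like chain of ``n_steps`` straight
    segments totalling ``contour_um``, with tangent-angle increments drawn
    from N(0, ds/Lp) — the discretization whose tangent correlation decays
    as exp(−s/(2·Lp)), matching the estimator's closed form."""
    ds = contour_um / n_steps
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    dtheta = rng.normal(0.0, np.sqrt(ds / lp_um), size=n_steps - 1)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    steps = ds * np.column_stack([np.cos(theta), np.sin(theta)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts


# ------------------------------------------------------------- fixtures


def single_bar_phantom(
    length_um: float,
    cal_um_per_px: float = 0.01,
    width_um: float = 0.05,
    angle_deg: float = 0.0,
) -> PhantomSpec:
    """One centered bar; used by the classification-threshold sweeps.

    The default bar is thin (0.05 µm) so its max-Feret length is its long
    axis rather than a width-inflated diagonal."""
    cal = PixelCalibration(cal_um_per_px)
    half_px = int(np.ceil(length_um / cal_um_per_px / 2.0)) + 10
    w = 2 * half_px + 1
    h = int(np.ceil(width_um / cal_um_per_px)) + 21
    cx = half_px * cal_um_per_px
    cy = -(h // 2) * cal_um_per_px
    return PhantomSpec(
        shape_px=(h, w),
        cal=cal,
        elements={"actinin": [Bar((cx, cy), length_um, width_um, angle_deg)]},
    )


def ladder_phantom(
    n: int,
    spacing_um: float,
    bar_length_um: float = 2.0,
    cal_um_per_px: float = 0.01,
    bar_width_um: float = 0.2,
) -> PhantomSpec:
    """Vertical ladder of horizontal bars: centers advance downward, so the
    chain axis is vertical and spacing equals the nominal value exactly
    when ``spacing_um`` is an integer number of pixels."""
    cal = PixelCalibration(cal_um_per_px)
    mpp = cal_um_per_px
    span = spacing_um * (n - 1)
    h = int(np.ceil((span + 2.0) / mpp)) + 1
    w = int(np.ceil((bar_length_um + 2.0) / mpp)) + 1
    cx = (w // 2) * mpp
    cy = -(h // 2) * mpp
    bars = ladder_bars(
        n, (cx, cy), bar_length_um, bar_width_um, 0.0, spacing_um, normal_deg=270.0
    )
    return PhantomSpec(shape_px=(h, w), cal=cal, elements={"actinin": bars})


def angle_pair_phantom(
    delta_deg: float,
    gap_um: float = 2.0,
    bar_length_um: float = 3.0,
    cal_um_per_px: float = 0.01,
    bar_width_um: float = 0.2,
) -> PhantomSpec:
    """Two bars ``gap_um`` apart along the first bar's normal; the second
    bar's long axis is rotated by ``delta_deg``."""
    cal = PixelCalibration(cal_um_per_px)
    mpp = cal_um_per_px
    ext = bar_length_um + gap_um + 2.0
    npix = int(np.ceil(ext / mpp)) + 1
    cx = (npix // 2) * mpp
    cy = -(npix // 2) * mpp
    b1 = Bar((cx, cy + gap_um / 2.0), bar_length_um, bar_width_um, 0.0)
    b2 = Bar((cx, cy - gap_um / 2.0), bar_length_um, bar_width_um, delta_deg)
    return PhantomSpec(
        shape_px=(npix, npix), cal=cal, elements={"actinin": [b1, b2]}
    )


def doublet_pair_phantom(
    member_length_um: float,
    pair_gap_um: float = 0.6,
    cal_um_per_px: float = 0.01,
    bar_width_um: float = 0.05,
) -> PhantomSpec:
    """Two parallel vertical titin lines ``pair_gap_um`` apart — a doublet
    when the members clear the titin length floor."""
    cal = PixelCalibration(cal_um_per_px)
    mpp = cal_um_per_px
    h = int(np.ceil((member_length_um + 2.0) / mpp)) + 1
    w = int(np.ceil((pair_gap_um + 2.0) / mpp)) + 1
    cx = (w // 2) * mpp
    cy = -(h // 2) * mpp
    bars = [
        Bar((cx - pair_gap_um / 2.0, cy), member_length_um, bar_width_um, 90.0),
        Bar((cx + pair_gap_um / 2.0, cy), member_length_um, bar_width_um, 90.0),
    ]
    return PhantomSpec(shape_px=(h, w), cal=cal, elements={"titin": bars})


def msf_row_phantom(
    angle_to_edge_deg: float,
    n_bodies: int = 5,
    spacing_um: float = 2.0,
    cal_um_per_px: float = 0.05,
    diameter_um: float = 0.6,
    cell_side_um: float = 40.0,
) -> PhantomSpec:
    """A row of Z-Bodies inside a square cell, tilted by
    ``angle_to_edge_deg`` relative to the bottom edge (tangent 0°). The row
    sits near the bottom edge so that edge is its perpendicular-foot
    reference."""
    cal = PixelCalibration(cal_um_per_px)
    mpp = cal_um_per_px
    margin = 5.0
    side_px = int(np.ceil((cell_side_um + 2 * margin) / mpp)) + 1
    x0, y_top = margin, -margin
    verts = square_cell_vertices(x0, y_top, cell_side_um)
    cy = y_top - cell_side_um + 4.0  # 4 µm above the bottom edge
    cx = x0 + cell_side_um / 2.0
    disks = body_row_disks(
        n_bodies, (cx, cy), diameter_um, spacing_um, angle_to_edge_deg
    )
    return PhantomSpec(
        shape_px=(side_px, side_px),
        cal=cal,
        elements={"actinin": disks},
        cell_vertices=verts,
    )


def composite_cell(cal_um_per_px: float = 0.1) -> tuple[PhantomSpec, GroundTruth]:
    """Three-modality composite: a 50 µm square cell containing two
    α-actinin-2 myofibrils (4 Z-Lines each) plus one unconfirmed Z-Line and
    one MSF of 3 Z-Bodies; a titin doublet ladder (4 doublets → 1 myofibril)
    plus two circular precursor rings; and one myomesin myofibril of 3
    M-Lines. All counts and nominal geometry are known by construction.
    """
    cal = PixelCalibration(cal_um_per_px)
    side = 50.0
    margin = 5.0
    verts = square_cell_vertices(margin, -margin, side)  # x 5..55, y -55..-5

    bar_l, bar_w = 2.0, 0.3
    # myofibril 1: vertical Z-Lines advancing along +x, center (17.7, -20)
    myof1 = ladder_bars(4, (17.7, -20.0), bar_l, bar_w, 90.0, 1.8, normal_deg=0.0)
    # myofibril 2: horizontal Z-Lines advancing along -y, center (35, -22.7)
    myof2 = ladder_bars(4, (35.0, -22.7), bar_l, bar_w, 0.0, 1.8, normal_deg=270.0)
    lone = Bar((45.0, -35.0), bar_l, bar_w, 0.0)  # unconfirmed potential Z-Line
    bodies = body_row_disks(3, (27.0, -51.0), 0.6, 2.0, 0.0)  # 4 µm above bottom

    # titin: doublet ladder (vertical members, pair gap 0.6, doublets 2 µm apart)
    titin_bars = []
    for k in range(4):
        x = 20.0 + 2.0 * k
        titin_bars.append(Bar((x - 0.3, -40.0), 2.0, 0.2, 90.0))
        titin_bars.append(Bar((x + 0.3, -40.0), 2.0, 0.2, 90.0))
    rings = [
        RingElement((40.0, -45.0), (2.0, 2.0), 0.4),
        RingElement((45.0, -45.0), (2.0, 2.0), 0.4),
    ]

    mlines = ladder_bars(3, (45.0, -21.8), 2.0, bar_w, 0.0, 1.8, normal_deg=270.0)

    spec = PhantomSpec(
        shape_px=(601, 601),
        cal=cal,
        elements={
            "actinin": myof1 + myof2 + [lone] + bodies,
            "titin": titin_bars + rings,
            "myomesin": mlines,
        },
        cell_vertices=verts,
    )
    truth = GroundTruth(
        elements={
            "actinin": [
                {"class": "zline", "length_um": bar_l, "n": 8},
                {"class": "unconfirmed_line", "length_um": bar_l, "n": 1},
                {"class": "zbody", "diameter_um": 0.6, "n": 3},
            ],
            "titin": [
                {"class": "doublet", "length_um": 2.0, "gap_um": 0.6, "n": 4},
                {"class": "ring", "diameter_um": 2.0, "aspect_ratio": 1.0, "n": 2},
            ],
            "myomesin": [{"class": "mline", "length_um": 2.0, "n": 3}],
        },
        expected={
            "n_myofibrils": 2,
            "n_zlines": 8,
            "n_msfs": 1,
            "n_zbodies": 3,
            "mean_zline_spacing_um": 1.8,
            "mean_zbody_spacing_um": 2.0,
            "mean_myofibril_relative_angle_deg": 0.0,
            "mean_myofibril_edge_distance_um": 17.5,
            "n_myofibrils_titin": 1,
            "n_doublets": 4,
            "mean_doublet_spacing_um": 2.0,
            "mean_titin_myofibril_relative_angle_deg": 0.0,
            "n_rings": 2,
            "mean_ring_diameter_um": 2.0,
            "mean_ring_aspect_ratio": 1.0,
            "n_myofibrils_myom": 1,
            "n_mlines": 3,
            "mean_mline_spacing_um": 1.8,
            "mean_myom_myofibril_relative_angle_deg": 0.0,
            "cell_area_um2": side**2,
            "mean_zline_length_um": bar_l,
            "mean_mline_length_um": 2.0,
            "mean_doublet_length_um": 2.0,
            "mean_zbody_length_um": 0.6,
        },
    )
    return spec, truth


def standard_suite() -> dict:
    """The named fixture set used by the test-suite and validation sweeps.

    Sweep entries carry ``values`` and a ``build(value)`` callable; static
    entries carry ``spec`` (and ``truth`` where counts are asserted).
    """
    suite: dict[str, dict] = {}
    suite["bar_length_sweep"] = {
        "values": np.round(np.arange(0.5, 3.0 + 1e-9, 0.01), 2),
        "build": single_bar_phantom,
        "brackets": (1.4, 1.7),
    }
    suite["ladder_spacing_sweep"] = {
        "values": np.round(np.arange(1.0, 4.0 + 1e-9, 0.05), 2),
        "build": lambda s: ladder_phantom(4, s),
        "brackets": (3.0,),
    }
    suite["pair_angle_sweep"] = {
        "values": np.arange(0.0, 61.0, 1.0),
        "build": angle_pair_phantom,
        "brackets": (30.0,),
    }
    suite["doublet_member_length_sweep"] = {
        "values": np.round(np.arange(1.0, 2.5 + 1e-9, 0.01), 2),
        "build": doublet_pair_phantom,
        "brackets": (1.7,),
    }
    suite["msf_row_angle_sweep"] = {
        "values": np.arange(0.0, 61.0, 1.0),
        "build": msf_row_phantom,
        "brackets": (30.0,),
    }

    # square cell with one myofibril parallel to the near edge
    cal = PixelCalibration(0.1)
    verts = square_cell_vertices(5.0, -5.0, 40.0)
    parallel = PhantomSpec(
        shape_px=(501, 501),
        cal=cal,
        elements={
            "actinin": ladder_bars(
                4, (25.0, -40.0), 2.0, 0.3, 90.0, 1.8, normal_deg=0.0
            )
        },
        cell_vertices=verts,
    )
    suite["square_cell_parallel_myofibril"] = {
        "spec": parallel,
        "truth": GroundTruth(expected={"n_myofibrils": 1, "relative_angle_deg": 0.0}),
    }
    # 45°-oblique myofibril: centroid displacement (1.3, -1.3) µm is an
    # integer number of pixels, so the chain axis is exactly 135° in the
    # image frame (45° to every edge of the square cell); bars at 45° so
    # the ladder stacks along their normal
    oblique = PhantomSpec(
        shape_px=(501, 501),
        cal=cal,
        elements={
            "actinin": [
                Bar((22.0 + 1.3 * k, -36.0 - 1.3 * k), 2.0, 0.3, 45.0)
                for k in range(4)
            ]
        },
        cell_vertices=verts,
    )
    suite["square_cell_oblique_myofibril"] = {
        "spec": oblique,
        "truth": GroundTruth(expected={"n_myofibrils": 1, "relative_angle_deg": 45.0}),
    }
    suite["msf_row_parallel"] = {
        "spec": msf_row_phantom(0.0),
        "truth": GroundTruth(expected={"n_msfs": 1, "n_zbodies": 5}),
    }
    suite["msf_row_oblique"] = {
        "spec": msf_row_phantom(60.0),
        "truth": GroundTruth(expected={"n_msfs": 0}),
    }

    cal01 = PixelCalibration(0.1)
    ring_spec = PhantomSpec(
        shape_px=(101, 101),
        cal=cal01,
        elements={"titin": [RingElement((5.0, -5.0), (2.0, 2.0), 0.4)]},
    )
    suite["circular_ring"] = {
        "spec": ring_spec,
        "truth": GroundTruth(
            expected={"n_rings": 1, "diameter_um": 2.0, "aspect_ratio": 1.0}
        ),
    }
    ell_spec = PhantomSpec(
        shape_px=(101, 101),
        cal=cal01,
        elements={"titin": [RingElement((5.0, -5.0), (4.0, 2.0), 0.4)]},
    )
    suite["elliptical_ring"] = {
        "spec": ell_spec,
        "truth": GroundTruth(expected={"n_rings": 1, "aspect_ratio": 2.0}),
    }

    spec, truth = composite_cell()
    suite["composite_cell"] = {"spec": spec, "truth": truth}
    return suite
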