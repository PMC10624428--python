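"""Titin doublets and precursor rings.

In an assembled sarcomere the titin I-band antibody labels two parallel
lines flanking each Z-Line — a *doublet*. Around the Z-Bodies of sarcomere
precursors the same stain instead forms closed *rings*. Ring detection is
topological (a hole-bearing titin structure is a ring, regardless of
length); among the remaining structures only lines longer than the titin
floor (1.7 µm, i.e. 0.3 µm above the Z-Line threshold, reflecting that
doublets extend slightly beyond their Z-Lines) are doublet-eligible.
Doublets then chain into myofibrils exactly like Z-Lines do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .assembly import Chain, chain_metrics, extract_chains, link_candidates
from .edges import CellOutline, min_distance_to_edge, relative_angle
from .io import PixelCalibration
from .morphometry import QuantParams, Structure, _aspect_ratio

__all__ = ["Doublet", "Ring", "pair_doublets", "assemble_doublet_myofibrils", "ring_metrics"]


@dataclass
class Doublet:
    """A paired pair of parallel titin lines flanking one Z-Line."""

    line_ids: tuple[int, int]
    centroid: tuple[float, float]  # midpoint, µm
    length_um: float  # mean member length
    orientation_deg: float  # circular mean of member orientations
    gap_um: float  # centroid separation of the pair


def _axial_mean(a_deg: float, b_deg: float) -> float:
    """Mean of two axial angles, taken along the shorter arc."""
    d = (b_deg - a_deg) % 180.0
    if d > 90.0:
        d -= 180.0
    return (a_deg + d / 2.0) % 180.0


def pair_doublets(
    lines: list[Structure], params: QuantParams
) -> tuple[list[Doublet], list[int]]:
    """Greedy mutual-nearest pairing of titin candidate lines into doublets.

    A candidate pair must have centroid gap ≤ ``doublet_pair_max_gap``,
    orientation difference ≤ ``doublet_pair_max_angle``, and displacement
    running along the lines' normals (the two members of a doublet stack
    laterally). Pairs are accepted in ascending gap order, each line used at
    most once; the leftover unpaired ids are returned alongside.
    """
    by_id = {s.id: s for s in lines}
    ids = sorted(by_id)
    candidates = []
    for a_idx, i in enumerate(ids):
        for j in ids[a_idx + 1 :]:
            a, b = by_id[i], by_id[j]
            gap = float(np.hypot(b.centroid[0] - a.centroid[0], b.centroid[1] - a.centroid[1]))
            if gap > params.doublet_pair_max_gap + params.dist_tol_um:
                continue
            if relative_angle(a.orientation_deg, b.orientation_deg) > (
                params.doublet_pair_max_angle + params.angle_tol_deg
            ):
                continue
            disp = float(
                np.rad2deg(
                    np.arctan2(
                        b.centroid[1] - a.centroid[1], b.centroid[0] - a.centroid[0]
                    )
                )
                % 180.0
            )
            ok = True
            for s in (a, b):
                normal = (s.orientation_deg + 90.0) % 180.0
                if relative_angle(disp, normal) > (
                    params.lateral_stack_angle + params.angle_tol_deg
                ):
                    ok = False
                    break
            if ok:
                candidates.append((gap, i, j))
    candidates.sort()
    used: set[int] = set()
    doublets: list[Doublet] = []
    for gap, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = by_id[i], by_id[j]
        doublets.append(
            Doublet(
                line_ids=(i, j),
                centroid=(
                    (a.centroid[0] + b.centroid[0]) / 2.0,
                    (a.centroid[1] + b.centroid[1]) / 2.0,
                ),
                length_um=(a.length_um + b.length_um) / 2.0,
                orientation_deg=_axial_mean(a.orientation_deg, b.orientation_deg),
                gap_um=gap,
            )
        )
    leftovers = [i for i in ids if i not in used]
    return doublets, leftovers


def _doublets_as_structures(doublets: list[Doublet]) -> list[Structure]:
    """Adapt doublets to the Structure interface the chain builder expects."""
    out = []
    for k, d in enumerate(doublets, start=1):
        out.append(
            Structure(
                id=k,
                centroid=d.centroid,
                length_um=d.length_um,
                orientation_deg=d.orientation_deg,
                orientation_degenerate=False,
                area_um2=1.0,
                aspect_ratio=1.0,
                has_hole=False,
                filled_area_um2=1.0,
                pixel_count=1,
                pixels=None,
            )
        )
    return out


def assemble_doublet_myofibrils(
    doublets: list[Doublet],
    params: QuantParams,
    outline: CellOutline | None = None,
) -> list[Chain]:
    """Chain doublets into titin myofibrils using the Z-Line linking rules,
    with the doublet minimum member count. Chain member ids index into the
    input doublet list (1-based)."""
    pseudo = _doublets_as_structures(doublets)
    adjacency = link_candidates(pseudo, params)
    chains = extract_chains(
        adjacency,
        pseudo,
        kind="myofibril",
        params=params,
        min_members=params.min_doublets_per_myofibril,
    )
    for c in chains:
        chain_metrics(c, pseudo, outline, params)
    return chains


@dataclass
class Ring:
    """A titin precursor ring (hole-bearing component), measured on its
    filled extent: the visible ring encircles a Z-Body, so the enclosed
    region is the biologically meaningful one."""

    structure_id: int
    centroid: tuple[float, float]
    diameter_um: float  # equivalent-circle diameter of the filled component
    aspect_ratio: float  # major/minor of the filled moment ellipse, >= 1
    edge_distance_um: float | None = None


def _filled_pixels(s: Structure) -> np.ndarray:
    pix = s.pixels
    r0, c0 = pix.min(axis=0)
    r1, c1 = pix.max(axis=0)
    sub = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    sub[pix[:, 0] - r0, pix[:, 1] - c0] = True
    filled = ndimage.binary_fill_holes(sub)
    rr, cc = np.nonzero(filled)
    return np.column_stack([rr + r0, cc + c0])


def ring_metrics(
    ring_structures: list[Structure],
    outline: CellOutline | None,
    cal: PixelCalibration,
) -> list[Ring]:
    """Measure precursor rings: equivalent-circle diameter
    ``2·sqrt(filled_area/π)``, moment-ellipse aspect ratio of the filled
    component (so "more rounded" reads as a value closer to 1), and — when
    an outline is given — distance from the ring centroid to the cell edge.
    """
    out: list[Ring] = []
    for s in ring_structures:
        if not s.has_hole:
            raise ValueError(f"structure {s.id} has no hole: not a ring")
        filled = _filled_pixels(s)
        diameter = 2.0 * np.sqrt(s.filled_area_um2 / np.pi)
        aspect = _aspect_ratio(filled)
        edist = None
        if outline is not None and outline.contains(s.centroid):
            edist = min_distance_to_edge(outline, s.centroid)
        out.append(
            Ring(
                structure_id=s.id,
                centroid=s.centroid,
                diameter_um=float(diameter),
                aspect_ratio=float(aspect),
                edge_distance_um=edist,
            )
        )
    return out
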