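"""Chaining structures into myofibrils and muscle stress fibers (MSFs).

A myofibril is a linear collection of four or more Z-Lines (three
sarcomeres). Candidate lines are linked pairwise when (1) their centroids
are < 3 µm apart, (2) their long axes differ by ≤ 30°, and (3) the
displacement between centroids runs roughly along the lines' normals (a
ladder stacks laterally; collinear end-to-end lines are one line, not a
myofibril). Connected components of the pruned link graph that reach the
minimum member count become confirmed chains; everything else stays
unconfirmed and is excluded from line-level reports.

Z-Bodies group into MSFs by a related rule: bodies < 3 µm apart whose
row direction is within 30° of the local cell-edge tangent.

Chain bendiness is summarized by a persistence length Lp obtained by
inverting the 2-D worm-like-chain end-to-end relation
``<R²> = 4·Lp·L − 8·Lp²·(1 − exp(−L/(2·Lp)))`` for the chain's contour
length L and end-to-end distance R; numerically straight chains are capped
at ``lp_cap``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Point

from .edges import CellOutline, min_distance_to_edge, nearest_edge_reference, relative_angle
from .morphometry import QuantParams, Structure

__all__ = [
    "Chain",
    "link_candidates",
    "extract_chains",
    "persistence_length",
    "chain_metrics",
    "group_msfs",
    "principal_axis_angle",
]


@dataclass
class Chain:
    """An ordered myofibril or MSF with its derived metrics."""

    kind: str  # "myofibril" | "msf"
    members: list[int]  # ordered structure (or doublet) ids
    centroids: np.ndarray = field(repr=False)  # (n, 2) µm, ordered
    n_members: int = 0
    mean_spacing_um: float | None = None
    mean_member_length_um: float | None = None
    contour_length_um: float | None = None
    end_to_end_um: float | None = None
    persistence_length_um: float | None = None
    long_axis_deg: float | None = None
    edge_distance_um: float | None = None
    edge_tangent_deg: float | None = None
    relative_angle_deg: float | None = None


def principal_axis_angle(points: np.ndarray) -> float:
    """Axial angle ([0, 180) from +x) of the principal axis of a point set."""
    pts = np.asarray(points, dtype=float)
    x = pts[:, 0] - pts[:, 0].mean()
    y = pts[:, 1] - pts[:, 1].mean()
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return float(np.rad2deg(theta) % 180.0)


def _link_admissible(a: Structure, b: Structure, params: QuantParams) -> bool:
    """Pairwise linking predicate for candidate lines (before pruning)."""
    ax, ay = a.centroid
    bx, by = b.centroid
    dist = float(np.hypot(bx - ax, by - ay))
    if not dist < params.max_link_gap - params.dist_tol_um:
        return False
    dori = relative_angle(a.orientation_deg, b.orientation_deg)
    if not dori <= params.max_link_angle + params.angle_tol_deg:
        return False
    # lateral-stacking check: centroid displacement must run within
    # lateral_stack_angle of both lines' normals
    disp = float(np.rad2deg(np.arctan2(by - ay, bx - ax)) % 180.0)
    for s in (a, b):
        normal = (s.orientation_deg + 90.0) % 180.0
        if not relative_angle(disp, normal) <= (
            params.lateral_stack_angle + params.angle_tol_deg
        ):
            return False
    return True


def link_candidates(
    lines: list[Structure], params: QuantParams
) -> dict[int, set[int]]:
    """Build the pruned link adjacency over candidate-line ids.

    Admissible pairs satisfy the gap/angle/lateral-stacking predicate; each
    node then keeps at most its nearest admissible neighbor on each side
    along its own normal (ties by smaller id), and an edge survives only if
    both endpoints keep it. The result is a graph of maximum degree 2, so
    chains are linear paths.
    """
    by_id = {s.id: s for s in lines}
    ids = sorted(by_id)
    admissible: dict[int, list[int]] = {i: [] for i in ids}
    for i_idx, i in enumerate(ids):
        for j in ids[i_idx + 1 :]:
            if _link_admissible(by_id[i], by_id[j], params):
                admissible[i].append(j)
                admissible[j].append(i)

    kept: dict[int, set[int]] = {i: set() for i in ids}
    for i in ids:
        si = by_id[i]
        normal = np.deg2rad(si.orientation_deg + 90.0)
        nvec = np.array([np.cos(normal), np.sin(normal)])
        best: dict[int, tuple[float, int]] = {}  # side -> (dist, id)
        for j in sorted(admissible[i]):
            sj = by_id[j]
            disp = np.array(sj.centroid) - np.array(si.centroid)
            side = 1 if float(disp @ nvec) >= 0 else -1
            dist = float(np.hypot(*disp))
            if side not in best or dist < best[side][0] - 1e-12:
                best[side] = (dist, j)
        kept[i] = {j for _, j in best.values()}

    adjacency: dict[int, set[int]] = {i: set() for i in ids}
    for i in ids:
        for j in kept[i]:
            if i in kept[j]:
                adjacency[i].add(j)
                adjacency[j].add(i)
    return adjacency


def extract_chains(
    adjacency: dict[int, set[int]],
    lines: list[Structure],
    kind: str,
    params: QuantParams,
    min_members: int | None = None,
) -> list[Chain]:
    """Confirmed chains = connected components of the link graph that reach
    the minimum member count for their kind; members are ordered by
    projection onto the component's principal axis."""
    if min_members is None:
        min_members = params.min_zlines_per_myofibril
    by_id = {s.id: s for s in lines}
    g = nx.Graph()
    g.add_nodes_from(adjacency)
    for i, nbrs in adjacency.items():
        for j in nbrs:
            g.add_edge(i, j)
    chains: list[Chain] = []
    for comp in sorted(nx.connected_components(g), key=min):
        if len(comp) < min_members:
            continue
        members = sorted(comp)
        pts = np.array([by_id[i].centroid for i in members])
        axis = np.deg2rad(principal_axis_angle(pts))
        proj = pts @ np.array([np.cos(axis), np.sin(axis)])
        order = np.argsort(proj, kind="stable")
        members = [members[k] for k in order]
        pts = pts[order]
        chains.append(
            Chain(kind=kind, members=members, centroids=pts, n_members=len(members))
        )
    return chains


def _wlc_r2(lp: float, L: float) -> float:
    """2-D worm-like-chain mean-square end-to-end distance."""
    return 4.0 * lp * L - 8.0 * lp**2 * (1.0 - np.exp(-L / (2.0 * lp)))


def persistence_length(centroids: np.ndarray, params: QuantParams) -> float:
    """Invert the 2-D worm-like-chain end-to-end relation for Lp (µm).

    L is the contour length through the ordered centroids, R the end-to-end
    distance. The relation is monotone in Lp (straighter is stiffer), so the
    root is found by bracketed bisection on (1e-3, lp_cap); chains with
    R/L > 0.999 are numerically straight and return ``lp_cap``.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("persistence length needs >= 3 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("consecutive centroids must be distinct")
    L = float(seg.sum())
    R = float(np.linalg.norm(pts[-1] - pts[0]))
    if R / L > 0.999:
        return params.lp_cap
    lo, hi = 1e-3, params.lp_cap
    f = lambda lp: _wlc_r2(lp, L) - R**2
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return params.lp_cap
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def chain_metrics(
    chain: Chain,
    lines: list[Structure],
    outline: CellOutline | None,
    params: QuantParams,
    member_lengths: dict[int, float] | None = None,
) -> Chain:
    """Fill a confirmed chain's derived metrics in place (and return it).

    Spacing is the mean consecutive centroid-to-centroid distance (centroid
    spacing, not parallel spacing). The long axis is the principal axis of
    the member centroids in the absolute image frame. Edge metrics are
    computed only when an outline is available: the reference edge is found
    perpendicular to the chain's long axis from its center point.
    """
    by_id = {s.id: s for s in lines}
    pts = chain.centroids
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    chain.mean_spacing_um = float(seg.mean())
    chain.contour_length_um = float(seg.sum())
    chain.end_to_end_um = float(np.linalg.norm(pts[-1] - pts[0]))
    if member_lengths is None:
        member_lengths = {i: by_id[i].length_um for i in chain.members}
    chain.mean_member_length_um = float(
        np.mean([member_lengths[i] for i in chain.members])
    )
    chain.long_axis_deg = principal_axis_angle(pts)
    if pts.shape[0] >= 3:
        chain.persistence_length_um = persistence_length(pts, params)
    if outline is not None:
        center = tuple(pts.mean(axis=0))
        if outline.contains(center):
            _, tangent, dist = nearest_edge_reference(
                outline, center, chain.long_axis_deg
            )
            chain.edge_distance_um = dist
            chain.edge_tangent_deg = tangent
            chain.relative_angle_deg = relative_angle(
                chain.long_axis_deg, tangent
            )
    return chain


def group_msfs(
    bodies: list[Structure],
    outline: CellOutline,
    params: QuantParams,
) -> list[Chain]:
    """Group candidate Z-Bodies into muscle stress fibers.

    Bodies i, j link when their centroids are < ``msf_max_gap`` apart and
    the i→j direction is within ``msf_edge_angle`` of the cell-edge tangent
    at the perpendicular foot of the body nearer to the edge ("rows of
    Z-Bodies parallel to the edge"). Components with at least
    ``min_bodies_per_msf`` members confirm as MSFs.
    """
    if outline is None:
        raise ValueError("MSF grouping requires a cell outline")
    by_id = {s.id: s for s in bodies}
    ids = sorted(by_id)
    # edge tangent at each body's nearest boundary point (perpendicular foot)
    tangent: dict[int, float] = {}
    edist: dict[int, float] = {}
    for i in ids:
        p = by_id[i].centroid
        if not outline.contains(p):
            edist[i] = np.inf
            tangent[i] = 0.0
            continue
        foot = outline.polygon.exterior.interpolate(
            outline.polygon.exterior.project(Point(p))
        )
        tangent[i] = outline.tangent_at_point((foot.x, foot.y))
        edist[i] = min_distance_to_edge(outline, p)

    g = nx.Graph()
    g.add_nodes_from(ids)
    for a_idx, i in enumerate(ids):
        for j in ids[a_idx + 1 :]:
            pi = np.array(by_id[i].centroid)
            pj = np.array(by_id[j].centroid)
            dist = float(np.linalg.norm(pj - pi))
            if not dist < params.msf_max_gap - params.dist_tol_um:
                continue
            near = i if edist[i] <= edist[j] else j
            if np.isinf(edist[near]):
                continue
            row_dir = float(
                np.rad2deg(np.arctan2(pj[1] - pi[1], pj[0] - pi[0])) % 180.0
            )
            if relative_angle(row_dir, tangent[near]) <= (
                params.msf_edge_angle + params.angle_tol_deg
            ):
                g.add_edge(i, j)

    msfs: list[Chain] = []
    for comp in sorted(nx.connected_components(g), key=min):
        if len(comp) < params.min_bodies_per_msf:
            continue
        members = sorted(comp)
        pts = np.array([by_id[i].centroid for i in members])
        axis = np.deg2rad(principal_axis_angle(pts))
        proj = pts @ np.array([np.cos(axis), np.sin(axis)])
        order = np.argsort(proj, kind="stable")
        members = [members[k] for k in order]
        pts = pts[order]
        chain = Chain(
            kind="msf", members=members, centroids=pts, n_members=len(members)
        )
        chain_metrics(chain, bodies, None, params)
        msfs.append(chain)
    return msfs
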