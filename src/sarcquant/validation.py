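"""Rule-recovery sweeps on phantoms.

Each routine renders a family of phantoms that brackets one of the
quantification rules' thresholds, runs the full pipeline on every member,
and reports the boundary it recovers — classification length floors, the
myofibril link gap and angle, minimum chain sizes, and the MSF edge-angle
criterion. They are the package's self-validation: the recovered boundary
must coincide with the configured rule.
"""

from __future__ import annotations

import numpy as np

from .assembly import link_candidates, persistence_length
from .edges import extract_outline
from .morphometry import QuantParams, classify_structure, label_structures
from .phantoms import (
    angle_pair_phantom,
    doublet_pair_phantom,
    ladder_phantom,
    msf_row_phantom,
    render,
    simulate_wlc_chain,
    single_bar_phantom,
)
from .pipeline import quantify_actinin
from .titin import pair_doublets

__all__ = [
    "recover_length_threshold",
    "recover_doublet_floor",
    "recover_link_gap",
    "recover_link_angle",
    "recover_msf_edge_angle",
    "minimum_chain_size",
    "wlc_median_estimates",
    "fragmentation_series",
]


def recover_length_threshold(
    stain: str,
    lengths: np.ndarray,
    params: QuantParams | None = None,
    cal_um_per_px: float = 0.01,
) -> float:
    """Render single bars at each nominal length, classify them, and return
    the supremum of nominal lengths classified below the line threshold."""
    params = params or QuantParams()
    sup = -np.inf
    for L in lengths:
        spec = single_bar_phantom(float(L), cal_um_per_px=cal_um_per_px)
        masks, _ = render(spec)
        (s,) = label_structures(masks["actinin"], spec.cal)
        if classify_structure(s, params, stain) == "candidate_body":
            sup = max(sup, float(L))
    return sup


def recover_doublet_floor(
    lengths: np.ndarray, params: QuantParams | None = None
) -> float:
    """Render titin line pairs with members at each nominal length and
    return the supremum of member lengths at which no doublet forms."""
    params = params or QuantParams()
    sup = -np.inf
    for L in lengths:
        spec = doublet_pair_phantom(float(L))
        masks, _ = render(spec)
        lines = [
            s
            for s in label_structures(masks["titin"], spec.cal)
            if classify_structure(s, params, "titin") == "candidate_line"
        ]
        doublets, _ = pair_doublets(lines, params)
        if not doublets:
            sup = max(sup, float(L))
    return sup


def recover_link_gap(
    spacings: np.ndarray, params: QuantParams | None = None
) -> float:
    """Render 4-bar ladders at each spacing and return the infimum spacing
    at which the ladder fails to confirm as one myofibril."""
    params = params or QuantParams()
    inf = np.inf
    for s in spacings:
        spec = ladder_phantom(4, float(s))
        masks, _ = render(spec)
        act = quantify_actinin(masks["actinin"], spec.cal, params)
        if len(act.myofibrils) != 1:
            inf = min(inf, float(s))
    return inf


def recover_link_angle(
    angles: np.ndarray, params: QuantParams | None = None
) -> float:
    """Render adjacent bar pairs at each relative orientation and return
    the largest angle at which the pair still links."""
    params = params or QuantParams()
    best = -np.inf
    for a in angles:
        spec = angle_pair_phantom(float(a))
        masks, _ = render(spec)
        act = quantify_actinin(masks["actinin"], spec.cal, params)
        adjacency = link_candidates(act.line_candidates, params)
        if sum(len(v) for v in adjacency.values()) // 2 == 1:
            best = max(best, float(a))
    return best


def recover_msf_edge_angle(
    angles: np.ndarray, params: QuantParams | None = None
) -> float:
    """Render Z-Body rows at each angle to the near cell edge and return
    the largest angle at which the row confirms as an MSF."""
    params = params or QuantParams()
    best = -np.inf
    for a in angles:
        spec = msf_row_phantom(float(a))
        masks, cell = render(spec)
        outline = extract_outline(cell, spec.cal)
        act = quantify_actinin(masks["actinin"], spec.cal, params, outline)
        if len(act.msfs) == 1:
            best = max(best, float(a))
    return best


def minimum_chain_size(kind: str, params: QuantParams | None = None) -> int:
    """Smallest ladder that confirms a chain of the given kind, found by
    rendering ladders of increasing size through the full pipeline."""
    params = params or QuantParams()
    for n in range(2, 7):
        if kind == "zline":
            spec = ladder_phantom(n, 1.8)
            masks, _ = render(spec)
            act = quantify_actinin(masks["actinin"], spec.cal, params)
            confirmed = len(act.myofibrils) == 1
        elif kind == "mline":
            from .mline import quantify_mlines

            spec = ladder_phantom(n, 1.8)
            masks, _ = render(spec)
            _, chains = quantify_mlines(masks["actinin"], spec.cal, params)
            confirmed = len(chains) == 1
        elif kind == "doublet":
            from .phantoms import Bar, PhantomSpec
            from .io import PixelCalibration
            from .titin import assemble_doublet_myofibrils

            cal = PixelCalibration(0.01)
            bars = []
            for k in range(n):
                x = 2.0 + 2.0 * k
                bars.append(Bar((x - 0.3, -2.0), 2.0, 0.05, 90.0))
                bars.append(Bar((x + 0.3, -2.0), 2.0, 0.05, 90.0))
            w = int((2.0 * n + 4.0) / 0.01)
            spec = PhantomSpec(shape_px=(401, w), cal=cal, elements={"titin": bars})
            masks, _ = render(spec)
            lines = [
                s
                for s in label_structures(masks["titin"], cal)
                if classify_structure(s, params, "titin") == "candidate_line"
            ]
            doublets, _ = pair_doublets(lines, params)
            chains = assemble_doublet_myofibrils(doublets, params)
            confirmed = len(chains) == 1
        else:
            raise ValueError(kind)
        if confirmed:
            return n
    return -1


def wlc_median_estimates(
    lp_values,
    contour_um: float,
    n_replicates: int,
    seed: int,
    n_steps: int = 60,
    params: QuantParams | None = None,
) -> dict[float, float]:
    """Median recovered persistence length over seeded worm-like-chain
    replicates, per true Lp."""
    params = params or QuantParams()
    rng = np.random.default_rng(seed)
    out = {}
    for lp in lp_values:
        estimates = [
            persistence_length(
                simulate_wlc_chain(lp, contour_um, n_steps, rng), params
            )
            for _ in range(n_replicates)
        ]
        out[float(lp)] = float(np.median(estimates))
    return out


def fragmentation_series(params: QuantParams | None = None):
    """Cells with progressively fragmenting ladders: at severity s, s of the
    6 ladders collapse to short, widely spaced puncta and the surviving
    Z-Lines shorten. Returns per-severity (myofibrils, Z-Lines, mean Z-Line
    length) — all three should fall monotonically, the direction of the
    contractility-inhibition phenotype."""
    from .phantoms import PhantomSpec, ladder_bars
    from .io import PixelCalibration

    params = params or QuantParams()
    cal = PixelCalibration(0.05)
    out = []
    for severity in range(4):
        bars = []
        for lad in range(6):
            cx = 8.0 + 6.0 * lad
            if lad < 6 - severity:
                length = 2.4 - 0.2 * severity
                spacing = 1.8 + 0.3 * severity
            else:
                length = 1.0  # below the Z-Line threshold
                spacing = 3.5  # beyond the link gap
            bars.extend(
                ladder_bars(4, (cx, -12.0), length, 0.2, 0.0, spacing, normal_deg=270.0)
            )
        spec = PhantomSpec(shape_px=(481, 921), cal=cal, elements={"actinin": bars})
        masks, _ = render(spec)
        act = quantify_actinin(masks["actinin"], cal, params)
        n_myof = len(act.myofibrils)
        n_zlines = sum(c.n_members for c in act.myofibrils)
        confirmed = {i for c in act.myofibrils for i in c.members}
        by_id = {s.id: s for s in act.line_candidates}
        mean_len = (
            float(np.mean([by_id[i].length_um for i in confirmed]))
            if confirmed
            else 0.0
        )
        out.append((n_myof, n_zlines, mean_len))
    return out
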