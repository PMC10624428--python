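"""End-to-end per-cell quantification: label → measure → classify →
assemble → report, one modality at a time.

The pipeline consumes binary masks (one stain per mask) plus an optional
cell-edge co-stain mask. Edge-relative metrics and MSF grouping are only
computed when the cell mask is present; without it those columns stay
empty, mirroring the fact that the sarcomeric stains do not label the cell
edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import Chain, chain_metrics, extract_chains, group_msfs, link_candidates
from .edges import CellOutline, extract_outline, min_distance_to_edge
from .io import PixelCalibration, read_mask
from .morphometry import QuantParams, Structure, classify_structure, label_structures
from .mline import quantify_mlines
from .report import ReportBundle, build_reports, write_csv
from .titin import Doublet, Ring, assemble_doublet_myofibrils, pair_doublets, ring_metrics

__all__ = [
    "ActininResult",
    "TitinResult",
    "MyomesinResult",
    "RunConfig",
    "quantify_actinin",
    "quantify_titin",
    "quantify_myomesin",
    "quantify_cell",
]

logger = logging.getLogger("sarcquant")


@dataclass
class ActininResult:
    structures: list[Structure]
    line_candidates: list[Structure]
    body_candidates: list[Structure]
    myofibrils: list[Chain]
    msfs: list[Chain]

    @property
    def n_unconfirmed_lines(self) -> int:
        confirmed = {i for c in self.myofibrils for i in c.members}
        return len(self.line_candidates) - len(confirmed)

    @property
    def n_unconfirmed_bodies(self) -> int:
        confirmed = {i for c in self.msfs for i in c.members}
        return len(self.body_candidates) - len(confirmed)


@dataclass
class TitinResult:
    structures: list[Structure]
    line_candidates: list[Structure]
    rings: list[Ring]
    doublets: list[Doublet]
    leftover_line_ids: list[int]
    myofibrils: list[Chain]
    doublet_edge_distances: list[float] = field(default_factory=list)


@dataclass
class MyomesinResult:
    structures: list[Structure]
    line_candidates: list[Structure]
    myofibrils: list[Chain]
    mline_edge_distances: list[float] = field(default_factory=list)
    cell_area_um2: float | None = None


def quantify_actinin(
    mask: np.ndarray,
    cal: PixelCalibration,
    params: QuantParams,
    outline: CellOutline | None = None,
) -> ActininResult:
    """Quantify an α-actinin-2 mask: Z-Lines chained into myofibrils,
    Z-Bodies grouped into MSFs (the latter only with a cell outline)."""
    structures = label_structures(mask, cal)
    lines = [
        s for s in structures if classify_structure(s, params, "actinin") == "candidate_line"
    ]
    bodies = [
        s for s in structures if classify_structure(s, params, "actinin") == "candidate_body"
    ]
    adjacency = link_candidates(lines, params)
    myofibrils = extract_chains(
        adjacency, lines, "myofibril", params,
        min_members=params.min_zlines_per_myofibril,
    )
    for c in myofibrils:
        chain_metrics(c, lines, outline, params)
    if outline is not None:
        msfs = group_msfs(bodies, outline, params)
    else:
        msfs = []
        if bodies:
            logger.warning(
                "no cell outline: %d Z-Body candidates not grouped into MSFs",
                len(bodies),
            )
    res = ActininResult(structures, lines, bodies, myofibrils, msfs)
    logger.info(
        "actinin: %d structures, %d line candidates (%d unconfirmed), "
        "%d myofibrils, %d body candidates (%d unconfirmed), %d MSFs",
        len(structures), len(lines), res.n_unconfirmed_lines,
        len(myofibrils), len(bodies), res.n_unconfirmed_bodies, len(msfs),
    )
    return res


def quantify_titin(
    mask: np.ndarray,
    cal: PixelCalibration,
    params: QuantParams,
    outline: CellOutline | None = None,
) -> TitinResult:
    """Quantify a titin mask: rings by topology, doublets by pairing,
    doublet chains as titin myofibrils."""
    structures = label_structures(mask, cal)
    ring_structs = [s for s in structures if s.has_hole]
    lines = [
        s
        for s in structures
        if classify_structure(s, params, "titin") == "candidate_line"
    ]
    rings = ring_metrics(ring_structs, outline, cal)
    doublets, leftovers = pair_doublets(lines, params)
    myofibrils = assemble_doublet_myofibrils(doublets, params, outline)
    edge_d: list[float] = []
    if outline is not None:
        for d in doublets:
            if outline.contains(d.centroid):
                edge_d.append(min_distance_to_edge(outline, d.centroid))
    res = TitinResult(
        structures, lines, rings, doublets, leftovers, myofibrils, edge_d
    )
    logger.info(
        "titin: %d structures, %d rings, %d line candidates, %d doublets "
        "(%d leftover lines), %d myofibrils",
        len(structures), len(rings), len(lines), len(doublets),
        len(leftovers), len(myofibrils),
    )
    return res


def quantify_myomesin(
    mask: np.ndarray,
    cal: PixelCalibration,
    params: QuantParams,
    outline: CellOutline | None = None,
) -> MyomesinResult:
    """Quantify a myomesin mask: M-Lines chained into myofibrils (minimum
    three M-Lines per myofibril)."""
    structures, myofibrils = quantify_mlines(mask, cal, params, outline)
    lines = [
        s
        for s in structures
        if classify_structure(s, params, "myomesin") == "candidate_line"
    ]
    confirmed = {i for c in myofibrils for i in c.members}
    edge_d: list[float] = []
    cell_area = None
    if outline is not None:
        cell_area = outline.area_um2
        for s in lines:
            if s.id in confirmed and outline.contains(s.centroid):
                edge_d.append(min_distance_to_edge(outline, s.centroid))
    res = MyomesinResult(structures, lines, myofibrils, edge_d, cell_area)
    logger.info(
        "myomesin: %d structures, %d M-Line candidates (%d confirmed), %d myofibrils",
        len(structures), len(lines), len(confirmed), len(myofibrils),
    )
    return res


_QUANTIFIERS = {
    "actinin": quantify_actinin,
    "titin": quantify_titin,
    "myomesin": quantify_myomesin,
}


@dataclass
class RunConfig:
    """One cell, one invocation: per-stain mask paths (at least one),
    optional cell mask, mandatory calibration, parameter overrides."""

    microns_per_pixel: float
    actinin_path: str | None = None
    titin_path: str | None = None
    myomesin_path: str | None = None
    cell_mask_path: str | None = None
    params: QuantParams = field(default_factory=QuantParams)
    out_dir: str = "."
    cell_id: str = "cell_1"

    def __post_init__(self) -> None:
        if not any((self.actinin_path, self.titin_path, self.myomesin_path)):
            raise ValueError("at least one stain mask is required")


def quantify_cell(cfg: RunConfig) -> ReportBundle:
    """Run the full pipeline for one cell and write the three CSVs."""
    cal = PixelCalibration(cfg.microns_per_pixel)
    outline = None
    if cfg.cell_mask_path:
        outline = extract_outline(read_mask(cfg.cell_mask_path), cal)
    results = {}
    sources = []
    for modality, path in (
        ("actinin", cfg.actinin_path),
        ("titin", cfg.titin_path),
        ("myomesin", cfg.myomesin_path),
    ):
        if path is None:
            continue
        mask = read_mask(path)
        results[modality] = _QUANTIFIERS[modality](mask, cal, cfg.params, outline)
        sources.append(Path(path).name)
    bundle = build_reports(results, cell_id=cfg.cell_id, source=";".join(sources))
    write_csv(bundle, cfg.out_dir)
    return bundle
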