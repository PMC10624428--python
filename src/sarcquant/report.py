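"""Report tables: per-cell, per-myofibril, per-MSF.

The metric registry is fixed at import time: 33 per-cell metrics
(13 α-actinin-2 + 11 titin + 9 myomesin), 24 per-myofibril metrics
(8 metrics × 3 stain modalities), and 3 per-MSF metrics — 60 unique
outputs in total. Modalities that were not quantified leave their columns
empty (not absent), and undefined averages (e.g., no confirmed myofibril)
are empty rather than zero, so "no myofibrils" is distinguishable from
"zero-length myofibrils".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PER_CELL_METRICS",
    "PER_MYOFIBRIL_METRICS",
    "PER_MSF_METRICS",
    "ReportBundle",
    "build_reports",
    "write_csv",
]

_ACTININ_CELL = [
    "n_myofibrils",
    "n_zlines",
    "mean_zline_length_um",
    "mean_zline_spacing_um",
    "mean_myofibril_persistence_um",
    "mean_myofibril_relative_angle_deg",
    "mean_myofibril_edge_distance_um",
    "n_msfs",
    "n_zbodies",
    "mean_zbody_length_um",
    "mean_zbody_spacing_um",
    "mean_msf_persistence_um",
    "mean_actinin_puncta_area_um2",
]
_TITIN_CELL = [
    "n_myofibrils_titin",
    "n_doublets",
    "mean_doublet_length_um",
    "mean_doublet_spacing_um",
    "mean_titin_myofibril_persistence_um",
    "mean_titin_myofibril_relative_angle_deg",
    "n_rings",
    "mean_ring_diameter_um",
    "mean_ring_aspect_ratio",
    "mean_doublet_edge_distance_um",
    "mean_ring_edge_distance_um",
]
_MYOM_CELL = [
    "n_myofibrils_myom",
    "n_mlines",
    "mean_mline_length_um",
    "mean_mline_spacing_um",
    "mean_myom_myofibril_persistence_um",
    "mean_myom_myofibril_relative_angle_deg",
    "mean_mline_edge_distance_um",
    "mean_myom_myofibril_edge_distance_um",
    "cell_area_um2",
]

PER_CELL_METRICS: list[str] = _ACTININ_CELL + _TITIN_CELL + _MYOM_CELL

_CHAIN_METRICS = [
    "n_lines",
    "mean_line_spacing_um",
    "persistence_length_um",
    "long_axis_deg",
    "mean_line_length_um",
    "edge_distance_um",
    "edge_tangent_deg",
    "relative_angle_deg",
]
_MODALITIES = ["actinin", "titin", "myomesin"]

PER_MYOFIBRIL_METRICS: list[str] = [
    f"{mod}_{m}" for mod in _MODALITIES for m in _CHAIN_METRICS
]

PER_MSF_METRICS: list[str] = [
    "n_zbodies",
    "mean_zbody_spacing_um",
    "persistence_length_um",
]


def _check_registry() -> None:
    for names, n in (
        (PER_CELL_METRICS, 33),
        (PER_MYOFIBRIL_METRICS, 24),
        (PER_MSF_METRICS, 3),
    ):
        if len(names) != n or len(set(names)) != n:
            raise AssertionError(
                f"metric registry corrupted: expected {n} unique names, "
                f"got {len(names)} ({len(set(names))} unique)"
            )
    # a per-cell count and a per-MSF count can share a short name (they are
    # different measurements at different granularity), so uniqueness of the
    # 60 outputs is table-qualified
    union = (
        {("cell", m) for m in PER_CELL_METRICS}
        | {("myofibril", m) for m in PER_MYOFIBRIL_METRICS}
        | {("msf", m) for m in PER_MSF_METRICS}
    )
    if len(union) != 60:
        raise AssertionError(
            f"metric registry corrupted: {len(union)} unique outputs, expected 60"
        )


_check_registry()


@dataclass
class ReportBundle:
    """The three output tables for one cell."""

    cell_table: pd.DataFrame
    myofibril_table: pd.DataFrame
    msf_table: pd.DataFrame


def _mean(values) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else None


def _chain_row(chain, modality: str) -> dict:
    row = {m: None for m in PER_MYOFIBRIL_METRICS}
    row[f"{modality}_n_lines"] = chain.n_members
    row[f"{modality}_mean_line_spacing_um"] = chain.mean_spacing_um
    row[f"{modality}_persistence_length_um"] = chain.persistence_length_um
    row[f"{modality}_long_axis_deg"] = chain.long_axis_deg
    row[f"{modality}_mean_line_length_um"] = chain.mean_member_length_um
    row[f"{modality}_edge_distance_um"] = chain.edge_distance_um
    row[f"{modality}_edge_tangent_deg"] = chain.edge_tangent_deg
    row[f"{modality}_relative_angle_deg"] = chain.relative_angle_deg
    return row


def build_reports(
    results: dict,
    cell_id: str = "cell_1",
    source: str = "",
) -> ReportBundle:
    """Assemble the three tables from per-modality quantification results.

    ``results`` maps modality name ("actinin", "titin", "myomesin") to the
    corresponding result object from :mod:`sarcquant.pipeline`. At least one
    modality is required. Per-cell averages run over confirmed objects only.
    """
    if not results:
        raise ValueError("at least one quantified modality is required")
    unknown = set(results) - set(_MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")

    cell = {m: None for m in PER_CELL_METRICS}
    myo_rows: list[dict] = []
    msf_rows: list[dict] = []

    act = results.get("actinin")
    if act is not None:
        cell["n_myofibrils"] = len(act.myofibrils)
        cell["n_zlines"] = sum(c.n_members for c in act.myofibrils)
        confirmed = {i for c in act.myofibrils for i in c.members}
        line_by_id = {s.id: s for s in act.line_candidates}
        cell["mean_zline_length_um"] = _mean(
            line_by_id[i].length_um for i in confirmed
        )
        cell["mean_zline_spacing_um"] = _mean(
            c.mean_spacing_um for c in act.myofibrils
        )
        cell["mean_myofibril_persistence_um"] = _mean(
            c.persistence_length_um for c in act.myofibrils
        )
        cell["mean_myofibril_relative_angle_deg"] = _mean(
            c.relative_angle_deg for c in act.myofibrils
        )
        cell["mean_myofibril_edge_distance_um"] = _mean(
            c.edge_distance_um for c in act.myofibrils
        )
        cell["n_msfs"] = len(act.msfs)
        confirmed_bodies = {i for c in act.msfs for i in c.members}
        cell["n_zbodies"] = len(confirmed_bodies)
        body_by_id = {s.id: s for s in act.body_candidates}
        cell["mean_zbody_length_um"] = _mean(
            body_by_id[i].length_um for i in confirmed_bodies
        )
        cell["mean_zbody_spacing_um"] = _mean(
            c.mean_spacing_um for c in act.msfs
        )
        cell["mean_msf_persistence_um"] = _mean(
            c.persistence_length_um for c in act.msfs
        )
        cell["mean_actinin_puncta_area_um2"] = _mean(
            s.area_um2 for s in act.structures
        )
        for k, c in enumerate(act.myofibrils, start=1):
            row = {"myofibril_id": f"{cell_id}_actinin_{k}", "modality": "actinin"}
            row.update(_chain_row(c, "actinin"))
            myo_rows.append(row)
        for k, c in enumerate(act.msfs, start=1):
            msf_rows.append(
                {
                    "msf_id": f"{cell_id}_msf_{k}",
                    "n_zbodies": c.n_members,
                    "mean_zbody_spacing_um": c.mean_spacing_um,
                    "persistence_length_um": c.persistence_length_um,
                }
            )

    tit = results.get("titin")
    if tit is not None:
        cell["n_myofibrils_titin"] = len(tit.myofibrils)
        cell["n_doublets"] = len(tit.doublets)
        cell["mean_doublet_length_um"] = _mean(d.length_um for d in tit.doublets)
        cell["mean_doublet_spacing_um"] = _mean(
            c.mean_spacing_um for c in tit.myofibrils
        )
        cell["mean_titin_myofibril_persistence_um"] = _mean(
            c.persistence_length_um for c in tit.myofibrils
        )
        cell["mean_titin_myofibril_relative_angle_deg"] = _mean(
            c.relative_angle_deg for c in tit.myofibrils
        )
        cell["n_rings"] = len(tit.rings)
        cell["mean_ring_diameter_um"] = _mean(r.diameter_um for r in tit.rings)
        cell["mean_ring_aspect_ratio"] = _mean(r.aspect_ratio for r in tit.rings)
        cell["mean_doublet_edge_distance_um"] = _mean(tit.doublet_edge_distances)
        cell["mean_ring_edge_distance_um"] = _mean(
            r.edge_distance_um for r in tit.rings
        )
        for k, c in enumerate(tit.myofibrils, start=1):
            row = {"myofibril_id": f"{cell_id}_titin_{k}", "modality": "titin"}
            row.update(_chain_row(c, "titin"))
            myo_rows.append(row)

    myo = results.get("myomesin")
    if myo is not None:
        cell["n_myofibrils_myom"] = len(myo.myofibrils)
        cell["n_mlines"] = sum(c.n_members for c in myo.myofibrils)
        confirmed = {i for c in myo.myofibrils for i in c.members}
        line_by_id = {s.id: s for s in myo.line_candidates}
        cell["mean_mline_length_um"] = _mean(
            line_by_id[i].length_um for i in confirmed
        )
        cell["mean_mline_spacing_um"] = _mean(
            c.mean_spacing_um for c in myo.myofibrils
        )
        cell["mean_myom_myofibril_persistence_um"] = _mean(
            c.persistence_length_um for c in myo.myofibrils
        )
        cell["mean_myom_myofibril_relative_angle_deg"] = _mean(
            c.relative_angle_deg for c in myo.myofibrils
        )
        cell["mean_mline_edge_distance_um"] = _mean(myo.mline_edge_distances)
        cell["mean_myom_myofibril_edge_distance_um"] = _mean(
            c.edge_distance_um for c in myo.myofibrils
        )
        cell["cell_area_um2"] = myo.cell_area_um2
        for k, c in enumerate(myo.myofibrils, start=1):
            row = {"myofibril_id": f"{cell_id}_myomesin_{k}", "modality": "myomesin"}
            row.update(_chain_row(c, "myomesin"))
            myo_rows.append(row)

    cell_row = {"cell_id": cell_id, "source": source}
    cell_row.update(cell)
    cell_table = pd.DataFrame([cell_row], columns=["cell_id", "source"] + PER_CELL_METRICS)
    myo_cols = ["myofibril_id", "modality"] + PER_MYOFIBRIL_METRICS
    myofibril_table = pd.DataFrame(myo_rows, columns=myo_cols)
    msf_cols = ["msf_id"] + PER_MSF_METRICS
    msf_table = pd.DataFrame(msf_rows, columns=msf_cols)
    return ReportBundle(cell_table, myofibril_table, msf_table)


def _format_value(v, col: str) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return ""
    try:
        if pd.isna(v):
            return ""
    except (TypeError, ValueError):
        pass
    if isinstance(v, str):
        return v
    if col.startswith("n_") or col.endswith("_n_lines"):
        return str(int(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return f"{float(v):.4f}"


def write_csv(bundle: ReportBundle, out_dir) -> dict[str, Path]:
    """Write ``cell.csv``, ``myofibrils.csv`` and ``msfs.csv``.

    Headers are exactly the registry names (after the id columns), floats
    carry 4 decimals, counts are bare integers, and undefined fields are
    empty strings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for fname, table in (
        ("cell", bundle.cell_table),
        ("myofibrils", bundle.myofibril_table),
        ("msfs", bundle.msf_table),
    ):
        path = out_dir / f"{fname}.csv"
        formatted = table.copy()
        for col in formatted.columns:
            formatted[col] = [_format_value(v, col) for v in formatted[col]]
        formatted.to_csv(path, index=False)
        paths[fname] = path
    return paths
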