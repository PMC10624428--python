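"""Myomesin M-Line quantification.

M-Lines sit at the midline of the thick-filament stack, between two
Z-Lines, and are stained by myomesin. Candidacy requires length > 1.4 µm
(same as Z-Lines), but a myomesin myofibril needs only three M-Lines —
three M-Lines imply at least four flanking Z-Lines, so the rule matches
the four-Z-Line minimum of the α-actinin-2 modality. Myomesin is absent
from Z-Bodies, so there is no body class and no MSF grouping here;
sub-threshold myomesin structures are only tallied as puncta.
"""

from __future__ import annotations

import numpy as np

from .assembly import Chain, chain_metrics, extract_chains, link_candidates
from .edges import CellOutline
from .io import PixelCalibration
from .morphometry import QuantParams, Structure, classify_structure, label_structures

__all__ = ["quantify_mlines"]


def quantify_mlines(
    mask: np.ndarray,
    cal: PixelCalibration,
    params: QuantParams,
    outline: CellOutline | None = None,
) -> tuple[list[Structure], list[Chain]]:
    """Label a myomesin mask and assemble M-Line myofibrils.

    Returns ``(structures, myofibrils)`` where ``structures`` are all
    labeled components (candidate M-Lines are those classified as lines)
    and ``myofibrils`` are confirmed chains of at least
    ``min_mlines_per_myofibril`` M-Lines, with edge metrics filled when an
    outline is supplied.
    """
    structures = label_structures(mask, cal)
    candidates = [
        s
        for s in structures
        if classify_structure(s, params, "myomesin") == "candidate_line"
    ]
    adjacency = link_candidates(candidates, params)
    chains = extract_chains(
        adjacency,
        candidates,
        kind="myofibril",
        params=params,
        min_members=params.min_mlines_per_myofibril,
    )
    for c in chains:
        chain_metrics(c, candidates, outline, params)
    return structures, chains
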