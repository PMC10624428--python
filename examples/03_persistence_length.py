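"""Persistence length of curved chains.

The bendiness of a myofibril (or MSF) is summarized by inverting the 2-D
worm-like-chain end-to-end relation for the chain of member centroids.
This script estimates Lp for centroids placed on circular arcs of known
radius and for simulated worm-like chains of known stiffness.
"""

import numpy as np

from sarcquant import QuantParams
from sarcquant.assembly import persistence_length
from sarcquant.phantoms import arc_points, simulate_wlc_chain

params = QuantParams()

print("arc-shaped chains (10 µm contour, 8 points):")
for radius in (3.0, 6.0, 12.0):
    pts = arc_points(radius, 8, 10.0)
    lp = persistence_length(pts, params)
    print(f"  radius {radius:5.1f} µm  ->  Lp = {lp:7.2f} µm")
print("tighter arcs bend more, so they report a shorter persistence length;")

straight = np.column_stack([np.arange(5) * 1.8, np.zeros(5)])
print(f"a perfectly straight chain caps at lp_cap = "
      f"{persistence_length(straight, params):.0f} µm.")

rng = np.random.default_rng(0)
print("\nsimulated worm-like chains (30 µm contour, 200 replicates):")
for lp_true in (5.0, 20.0):
    est = [
        persistence_length(simulate_wlc_chain(lp_true, 30.0, 300, rng), params)
        for _ in range(200)
    ]
    print(f"  true Lp {lp_true:5.1f} µm  ->  median estimate {np.median(est):6.2f} µm")
print("Single-chain estimates scatter (and their median sits above the "
      "truth for stiff chains); the ensemble mean R² is the unbiased "
      "quantity the formula describes.")
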