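"""Titin structures: precursor rings vs doublets.

Renders a titin mask holding one circular ring, one elongated ring, and a
ladder of four doublets, then shows how topology (a hole) routes a
structure to ring metrics while paired parallel lines become doublets and
chain into a myofibril.
"""

import sarcquant as sq
from sarcquant import phantoms as ph

cal = sq.PixelCalibration(0.05)
elements = [
    ph.RingElement((4.0, -4.0), (2.0, 2.0), 0.4),
    ph.RingElement((10.0, -4.0), (4.0, 2.0), 0.4),
]
for k in range(4):
    x = 4.0 + 2.0 * k
    elements.append(ph.Bar((x - 0.3, -12.0), 2.0, 0.2, 90.0))
    elements.append(ph.Bar((x + 0.3, -12.0), 2.0, 0.2, 90.0))

spec = ph.PhantomSpec(shape_px=(361, 361), cal=cal, elements={"titin": elements})
masks, _ = ph.render(spec)

res = sq.quantify_titin(masks["titin"], cal, sq.QuantParams())
print(f"rings detected: {len(res.rings)}")
for r in res.rings:
    print(f"  diameter {r.diameter_um:4.2f} µm, aspect ratio {r.aspect_ratio:4.2f}")
print(f"doublets detected: {len(res.doublets)} "
      f"(gaps {[round(d.gap_um, 2) for d in res.doublets]})")
print(f"titin myofibrils: {len(res.myofibrils)} "
      f"({res.myofibrils[0].n_members} doublets, "
      f"spacing {res.myofibrils[0].mean_spacing_um:.2f} µm)")
print("The circular ring reports aspect ≈ 1, the stretched ring ≈ 2 — the "
      "readout that distinguishes rounded precursor rings from elongated "
      "ones. The four doublets chain into one myofibril.")
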