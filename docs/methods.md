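# Methods

## The measurement problem

During de novo sarcomere assembly in cultured cardiac myocytes, the actin
bundler α-actinin-2 marks two populations at once: punctate **Z-Bodies**
inside muscle stress fibers (MSFs, the sarcomere precursors near the cell
edge) and elongated **Z-Lines** of assembled sarcomeres deeper in the cell.
Titin marks paired I-band lines (**doublets**) flanking each Z-Line in
assembled sarcomeres and closed **precursor rings** around Z-Bodies;
myomesin marks the **M-Line** at the thick-filament midline. `sarcquant`
quantifies all of these in real space from binary masks: it classifies
structures, chains them into myofibrils and MSFs, measures orientation
relative to the cell edge, and writes per-cell / per-myofibril / per-MSF
tables. Binarization itself is treated as an upstream concern: a classical
Otsu reference binarizer is provided, and externally produced masks (e.g.,
from a learned segmenter) drop in unchanged.

## Geometry conventions

Images are indexed 0-based `(row, col)` with pixel centers at integer
coordinates; physical coordinates are `(x, y) = (c·mpp, −r·mpp)` with `mpp`
the mandatory isotropic calibration in µm/px (never read from TIFF tags).
All angles are axial — degrees in [0, 180) from +x, counterclockwise
positive — and axial differences are folded into [0, 90]
(`relative_angle`). Foreground connectivity is 8-connected everywhere.

## Per-structure measurements

* **Length** is the max-Feret diameter: the maximum pairwise distance
  between member pixel centers (computed on the convex hull). It is
  deterministic and parameter-free; for a finite-width bar it includes the
  width diagonal, which is why validation phantoms near a length threshold
  are drawn thin.
* **Orientation** is the principal axis of the pixel second central
  moments; a single pixel (or perfectly isotropic set) reports 0° with a
  degeneracy flag.
* **Aspect ratio** is major/minor of the moment ellipse with each pixel
  contributing its unit-square variance (1/12 per axis), so small round
  structures behave sensibly instead of degenerating.
* **Hole topology**: a structure has a hole iff filling it grows its area
  by more than one pixel — the threshold-free test that routes titin
  structures to ring metrics. Ring diameter is the equivalent-circle
  diameter of the *filled* component (the ring encircles a Z-Body, so the
  enclosed region is the biologically meaningful extent); ring aspect
  ratio ≥ 1, so "more rounded" reads as a value closer to 1.
* Structures touching the image border are measured normally; users should
  crop or exclude heavily clipped cells themselves.

## Classification and chaining rules (the tool's parameters)

All parameters live in `QuantParams` and are user-settable; the defaults
are the rules the tool is built around:

| parameter | default | meaning |
| --- | --- | --- |
| `zline_min_len` | 1.4 µm | α-actinin-2 structure is a potential Z-Line iff length strictly exceeds this; otherwise a potential Z-Body |
| `titin_line_min_len` | 1.7 µm | titin line floor for doublet eligibility (doublets extend ~0.3 µm beyond their Z-Lines) |
| `mline_min_len` | 1.4 µm | M-Line candidacy floor |
| `max_link_gap` | 3.0 µm | centroid-to-centroid distance must be strictly below this to link two lines |
| `max_link_angle` | 30° | maximum long-axis difference between linked lines (inclusive) |
| `min_zlines_per_myofibril` | 4 | a myofibril is a linear collection of ≥ 4 Z-Lines (3 sarcomeres) |
| `min_doublets_per_myofibril` | 4 | same rule on titin doublets |
| `min_mlines_per_myofibril` | 3 | 3 M-Lines imply ≥ 4 flanking Z-Lines |
| `msf_max_gap` | 3.0 µm | Z-Body link distance within an MSF (strict <) |
| `msf_edge_angle` | 30° | Z-Body row direction vs local edge tangent (inclusive) |
| `min_bodies_per_msf` | 3 | smallest MSF (two spacings are needed for spacing/Lp to mean anything) |
| `doublet_pair_max_gap` | 1.0 µm | centroid separation of a doublet's two lines — well under one sarcomere spacing |
| `doublet_pair_max_angle` | 15° | orientation difference within a doublet |
| `lateral_stack_angle` | 45° | centroid displacement must lie within this of both lines' normals (a ladder stacks laterally; collinear end-to-end lines are one line, not a myofibril) |
| `lp_cap` | 500 µm | persistence length reported for numerically straight chains |

Linking builds an undirected graph over candidate lines (gap ∧ angle ∧
lateral-stacking), then prunes each node to its nearest admissible
neighbor on each side along its own normal (ties to the smaller id; an
edge survives only if both endpoints keep it). The result has maximum
degree 2, so chains are linear paths — the operational form of "linear
collection". Connected components reaching the kind's minimum confirm;
everything else stays unconfirmed and is excluded from line-level
averages (unconfirmed counts are logged). Chain members are ordered by
projection onto the principal axis of their centroids.

Doublet pairing is greedy mutual-nearest: candidate pairs (gap ≤ 1 µm,
angle ≤ 15°, lateral stacking) are accepted in ascending gap order with
each line used once; leftovers are tallied but excluded from doublet and
myofibril metrics. Rings take precedence over doublet eligibility — the
classes are exclusive.

MSF grouping links two Z-Bodies when they are closer than `msf_max_gap`
and the direction between them lies within `msf_edge_angle` of the edge
tangent at the perpendicular foot of whichever body is nearer the edge
("rows parallel to the edge" is a local statement; edges curve).

### Numerical guards

Strict threshold comparisons carry two guards: `dist_tol_um` (5 nm) and
`angle_tol_deg` (0.05°). A strict `<` on distance is evaluated as
`d < threshold − dist_tol`, a strict `>` on length as
`L > threshold + dist_tol`, and an inclusive `≤` on angle as
`a ≤ threshold + angle_tol`. Measured rasterization error is ≤ 0.07 px in
centroids and ≤ 0.04° in moment orientations; without the guards a
structure rendered *exactly at* a threshold would land on an arbitrary
side of it depending on float rounding. The guards are 2–3 orders of
magnitude below any biologically meaningful difference and below the
resolutions at which the thresholds are swept.

## Edge-relative orientation

The cell outline comes from a co-stain mask: largest component,
hole-filled, traced by marching squares at the 0.5 level, simplified with
a 0.4 px tolerance (just under the half-pixel corner-cut depth, so
collinear contour points collapse while corner vertices survive and long
straight edges keep their exact axis-aligned tangent — a 0.5 px tolerance
would tilt a 50 µm edge by ~0.06°). For a myofibril, rays are cast from
the chain center in both directions perpendicular to its long axis; the
nearer boundary intersection supplies the reference edge segment, its
tangent, and the edge distance. The reported orientation is the folded
difference between chain axis and edge tangent: 0° = parallel, 90° =
perpendicular. This perpendicular-ray reading operationalizes "nearest
parallel edge": the edge found along a myofibril's normal is, for a
parallel myofibril, the parallel edge. For point queries (ring/doublet
edge distances) the unconstrained minimum distance to the polygon is used
instead, which is never larger than the perpendicular-constrained one.

## Persistence length

Chain bendiness is summarized by inverting the 2-D worm-like-chain
end-to-end relation

    ⟨R²⟩ = 4·Lp·L − 8·Lp²·(1 − exp(−L / (2·Lp)))

for the chain of member centroids, with L the contour length (sum of
consecutive centroid distances) and R the end-to-end distance. The right
side is monotone in Lp (straighter is stiffer), so the root is bracketed
and found by `brentq` on (10⁻³, `lp_cap`); chains with R/L > 0.999 are
numerically straight and report `lp_cap`. At least 3 points are required.

Caveat on validation: applied to a *single* chain, this inversion treats
one realization's R² as the ensemble mean. Across simulated worm-like
chains the ensemble-mean R² matches the closed form (sampler and formula
agree to <0.5%), but the per-chain estimate distribution is skewed: R² is
left-skewed (R ≤ L), its median exceeds its mean, and the median estimate
therefore overshoots the true Lp — mildly in the flexible regime,
by ~30% when Lp ≫ L (e.g., Lp = 80 µm at L = 30 µm). Single-chain Lp
values should be compared between conditions, not read as unbiased
stiffness estimates of stiff chains; the test suite asserts both the
ensemble-level agreement and this documented bias boundary.

## Synthetic phantoms

Phantoms rasterize analytic primitives (bars, disks, elliptical annuli,
ladders, body rows, polygonal cells) by pixel-center containment — a pixel
belongs to an element iff its center does (with a 10⁻⁹ boundary epsilon so
nominal sizes rasterize to their intended extent). Rendering is
deterministic and platform-independent. The default 0.1 µm/px calibration
(0.01 µm/px in threshold sweeps) places the rule thresholds tens to
hundreds of pixels away from rasterization error. Phantoms for exact-angle
assertions place centroids at integer pixel offsets (e.g., displacement
(1.3, −1.3) µm at 0.1 µm/px) so chain axes are exact in floating point.
Curved-chain references place centroids on circular arcs, for which
contour and end-to-end lengths are analytic. A discrete worm-like-chain
sampler (tangent increments N(0, ds/Lp), matching the exp(−s/2Lp)
correlation of the estimator's closed form) provides known-stiffness
chains.

What phantoms do *not* emulate: optics (PSF blur, noise, intensity
gradients), segmentation errors, curved or branched myofibrils, touching
structures, and 3-D geometry. Passing phantom tests therefore certifies
the *quantification rules* — classification, chaining, measurement,
reporting — not robustness to imperfect binarization, which is the
upstream segmenter's responsibility.

## Reports

The metric registry is frozen at import: 33 per-cell metrics
(13 α-actinin-2 + 11 titin + 9 myomesin), 24 per-myofibril metrics (8 ×
3 stain modalities), 3 per-MSF metrics — 60 outputs. Per-cell averages run
over confirmed objects only; a cell without confirmed myofibrils leaves
the myofibril-average fields empty rather than zero, so "no myofibrils"
is distinguishable from "zero-valued myofibrils". Missing modalities leave
their columns empty, not absent. CSVs carry 4-decimal floats, bare-integer
counts, and empty strings for undefined values; identical inputs and
parameters produce byte-identical files.

## Problem sizes used in validation

Threshold sweeps run 0.5–3.0 µm in 0.01 µm steps at 0.01 µm/px; spacing
sweeps 1.0–4.0 µm (0.01–0.05 µm steps); angle sweeps 0–60° in 1° steps;
worm-like-chain recovery uses 200 replicates of 300-segment chains per
stiffness. These sizes localize every boundary to one sweep step while
keeping the full validation suite under a minute of compute.

## Known limitations

* 2-D only; single cell per image (multi-cell fields must be cropped).
* Centroid spacing, not parallel spacing, is reported (faster; slightly
  different when lines are long and oblique to the chain axis).
* Skeleton arc-length is not implemented as a length estimator; strongly
  curved single structures are summarized by their Feret diameter.
* Degree-2 pruning enforces linearity; genuinely branched myofibrils are
  split at the branch point.
* The binarizer is a reference implementation; the package's accuracy on
  real micrographs is bounded by the quality of the masks it is given.
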