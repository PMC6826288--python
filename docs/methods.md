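# Methods

`wingmorph` quantifies insect-wing morphology with a small set of
scale-free geometric and topological statistics computed from a polygonal
reconstruction of the wing: the outer contour, the tessellation of the
membrane into vein-bounded domains, and the venation graph. This note
documents the model, the parameters that matter, the numerical choices, and
the known limitations.

## Area normalization and the morphospace statistics

Absolute wing size correlates with body size and is deliberately removed:
every wing is rescaled so its boundary encloses area `A = 1` before any
statistic is computed. The whole-wing morphospace is then spanned by

* **Normalized perimeter** `P = P̃/√A − 2√π`, where `P̃` is the boundary
  perimeter. The offset is the circumference of the unit-area circle, so a
  circle scores exactly 0 and the isoperimetric inequality guarantees
  `P ≥ 0` for every simple contour; `P` grows with elongation and boundary
  complexity.
* **Internal vein length** `L`: the summed length of all venation-graph
  edges minus the boundary perimeter (computed separately), scaled by `√A`.
  A circular wing with no internal venation sits at the morphospace origin
  `(P, L) = (0, 0)`. `L/P̃` (perimeter-scaled) is reported alongside.
  Tiny negative residuals of the subtraction are clamped to zero; a clamp
  beyond `1e-6·P̃` emits a warning because it indicates a malformed graph.
* **Contour curvature** `κ(s)`: the boundary is resampled uniformly by arc
  length and, for each sample `p_i`, a circle is fitted through
  `p_{i−N}, p_i, p_{i+N}` where `N` corresponds to an arc distance of
  `window·P̃` (default window 0.02). `κ = 1/R`, reported as an absolute
  value; the three-point algebraic (Kåsa) fit is closed-form and exact for
  points on a true circle. With `scaled=True` the profile is multiplied by
  `P̃`, making it dimensionless (a circle scores `2π` everywhere). The
  parameter `s ∈ [0, 1)` is the clockwise arc-length fraction from the wing
  base; the base is the leftmost boundary point after rotating the long
  (principal) axis horizontal, with ties broken by the lowest y.

**Curvature bias.** The windowed three-point fit underestimates curvature
peaks by `O(window²)`: on a 2:1 ellipse the maximum-curvature error is
2.6% at window 0.02, 0.7% at 0.01 and 0.2% at 0.005 (the ratio ≈ 4 per
halving is unit-tested). Validation of curvature extrema against closed
forms therefore uses window 0.005; profiles meant to mirror the default
analysis use 0.02 and inherit the corresponding peak attenuation.

## Domains

Each vein-bounded domain contributes two dimensionless numbers: the
isoperimetric quotient **circularity** `c = 4πa/p² ∈ (0, 1]` (1 for a
circle, decreasing toward 0 with elongation) and the **fractional area**
`f = a/A`. The equivalent "perimeter over equal-area circumference" index
equals `c^(−1/2)` and is available as `DomainStats.perimeter_ratio`.
Zero-area domains are excluded with a warning.

The **proximal–distal trace** slices the wing into `n_bins` (default 25)
equal-width slabs perpendicular to the long axis. For bin `i` and domain
`j`, the overlap fraction `f_ij` is the share of the domain's area inside
the slab (rows of the overlap matrix sum to 1 by construction). With
weights `w_ij = f_ij·a_j`, the trace reports the weighted mean area
`Σ_j w_ij a_j / Σ_j w_ij` and mean circularity `Σ_j w_ij c_j / Σ_j w_ij`
per bin. Empty bins carry NaN and are excluded from smoothing. Smoothing
is a discrete Gaussian of standard deviation `sigma` in span units
(default 2/25, i.e. two bins), reflected at the ends — a convex
combination, so smoothed values stay inside the raw range. An optional
flag rescales the mean-area series by the wing perimeter.

The base end of the axis is chosen as the half of the span holding the
*sparser* vertex cluster: in densely veined wings, cross-venation (and
hence junction density) concentrates distally and toward the trailing
edge, so the crowded half is read as the tip. An explicit orientation
override is available by pre-rotating the wing.

## Venation network

The polygonal reconstruction yields two graph views:

* the **segment graph** (the `SegmentedWing.edges` default): every polygon
  vertex is a node, every unique ring edge a graph edge. This is the graph
  used for internal vein length, where it makes `L` an exact sum of shared
  polygon-edge lengths.
* the **junction graph** (`junction_graph()` /
  `build_adjacency(..., junctions_only=True)`): degree-2 vertices are
  collapsed into polyline edges, so nodes are vein junctions and edges
  whole vein stretches. Junction-free cycles (a venation-free boundary)
  are split at two anchors so edge endpoints stay distinct.

Adjacency weightings: `unweighted` (`M_ij = 1`), `inverse_length`
(`1/Lⁿ`, `n ∈ {1, 2}`, `L` the polyline length), and `resistance`, the
Poiseuille-style vein resistance `L/r⁴` stored as the conductance `r⁴/L`
so that short, wide veins couple nodes strongly (adjacency weights
conventionally encode coupling strength). Vein radii can be supplied
per edge or interpolated from sparse field measurements by inverse-
distance weighting (power 2) at edge midpoints; a single sample gives a
constant field.

Community structure maximizes Newman modularity
`Q = (1/2m) Σ_ij [M_ij − k_i k_j/(2m)] δ(c_i, c_j)`. Two optimizers are
provided: an exhaustive search over set partitions (exact, capped at 12
nodes; automatic for ≤ 10) and a deterministic greedy agglomeration
(CNM-style: repeatedly merge the connected community pair with the largest
`ΔQ = 2(e_ij − a_i a_j)`, lexicographic tie-break, stop at no positive
gain). If a greedy result ends below `Q = 0` the trivial single community
is returned, so `Q ≥ 0` always holds. The returned `Q` is recomputed from
the returned labels, and the partition records which optimizer produced
it. On the synthetic battery, junction-graph community counts grow with
venation density (4 → 15 communities from 10 → 500 domains), mirroring
the sparse-fly/dense-dragonfly contrast.

## Image segmentation

Images follow the convention bright = membrane, dark = vein, row 0 = top;
intensities are rescaled to [0, 1] on load and converted to a y-up plane.

1. **Thresholding** (default 0.5) labels 4-connected bright components,
   discarding speckle below `min_size` (default 25 px).
2. **Silhouette**: the bright mask is morphologically closed (radius 5 px)
   over vein gaps, hole-filled, and dilated outward by `boundary_pad`
   (default 1.5 px ≈ half a typical boundary-vein width) so the recovered
   outline sits on the boundary-vein centreline rather than its inner edge.
3. **Front propagation**: one seed per component (deterministically the
   most interior pixel; optionally a seeded random interior pixel, or
   user-supplied) expands with speed `ε + (1−ε)·I^γ` (defaults ε = 0.02,
   γ = 2): fast across membrane, crawling through veins, so fronts meet
   near vein midlines. First arrival is computed exactly with Dijkstra on
   the 4-connected grid (`skimage.graph.MCP_Geometric`), which also makes
   every labeled region 4-connected and the result deterministic.
4. **Polygonization**: region boundaries are traced on the pixel-corner
   lattice and cut into chains at junction corners (≥ 3 regions, or 2
   regions + background). Internal corners are then moved to the subpixel
   locus where the two fronts arrive simultaneously — the offset along the
   pixel-pair axis is `(t_b − t_a)/(2c)` with `c` the mean traversal cost,
   capped below half a pixel; corners average the offsets of their incident
   segments. Each chain is Douglas–Peucker simplified once (tolerance
   0.5 px, ≤ 1 px allowed, endpoints preserved) and shared by both
   adjacent regions, so common edges have identical coordinates in both
   rings and non-convex regions survive unharmed. The outer contour is
   recovered from the segments bordering the background.

Parameter guidance: `ε` trades midline accuracy (small ε sharpens the
meeting line) against robustness of huge domains to seed placement (a
front can cross a vein of width `w` at cost `w/ε` and annex membrane
whose own seed is farther away in travel time); with ε = 0.02 and 3 px
veins the partition is seed-placement-invariant for domains up to roughly
150 px across. `γ` sharpens the membrane/vein contrast and matters only
for noisy gray images.

## Synthetic wings

The generator emulates the range from sparse fly-like to dense
dragonfly-like venation with exact ground truth. A smooth boundary
(circle, ellipse with aspect ratio, or a teardrop whose chord tapers
toward the base) is tessellated by a Lloyd-relaxed (2 iterations),
boundary-clipped Voronoi partition of `n_domains` seed points; seed
density can increase base→tip and leading→trailing edge by exponential
gradient factors. Everything is deterministic per seed. The canonical
12-fixture battery spans 1–500 domains, all three boundary shapes, and
uniform vs 3× tip-ward gradients with pinned seeds.

Rasterization draws the membrane at 0.95, veins (all graph edges,
boundary included, buffered to `vein_width_px`) and background at 0.05,
with hard fills and no anti-aliasing; the default test resolution is a
1200 px span with 3 px veins.

What the generator does **not** emulate: longitudinal-vein hierarchy,
corrugation, pigmentation, imaging noise, blur, or uneven illumination.
Segmentation results on these clean rasters therefore bound what the
front-propagation method can do, not what scanned micrographs will give;
the threshold/ε/γ defaults were chosen for clean, high-contrast input.

Resolution limits observed on the battery round trip (generate →
rasterize at 1200 px → segment → compare): domain counts are recovered
exactly up to 500 domains and per-domain fractional areas to within 5%
(typically ≤ 2%); the hardest cases are ~400 px² domains whose ~3 px
veins occupy a large share of their neighborhood.

## Numerical choices

* Degenerate curvature triples (collinear points) give κ = 0, not an error.
* Vertex snapping when assembling tessellations uses a KD-tree union-find
  at tolerance 1e-7 (1e-9 for lattice-derived rings, which share exact
  coordinates by construction).
* Validation tolerances: domain areas must tile the boundary to 1% of the
  wing area; normalized wings must have area 1 within 1e-6.
* The wing CSV stores integer coordinates on a caller-chosen grid
  (default 1.0); writing refuses quantizations that merge vertices, and
  reading re-derives the graph from the rings, so round trips preserve
  topology exactly and coordinates to half a grid step.
* PD-trace slab edges are widened by 1e-9 of the span at the two extremes
  so boundary-touching polygons are never dropped by exact-equality
  clipping.
* Batch measurement never raises on a bad input: the record is flagged
  with the failing stage and the run continues; tables are sorted by wing
  id so reruns are byte-identical.

## Problem sizes

Tests and the acceptance suite run on the 12-fixture battery (≤ 500
domains, 1200 px rasters), 10,000-gon analytic contours, and ≤ 8-node
graphs for exhaustive community oracles; the complete suite takes about a
minute on one CPU.

## Known limitations

* Exact community optimization is infeasible beyond 12 nodes; larger
  graphs rely on the greedy optimizer, which is deterministic but can be
  suboptimal (the partition records its method for auditability).
* The curvature window trades noise suppression against peak attenuation;
  there is no adaptive window.
* The P–D base-end heuristic assumes venation density increases distally;
  for wings where it does not, pre-orient the wing before tracing.
* `resistance` weighting needs radii; none are inferred from images.
* Segmented boundaries are limited by rasterization: subpixel refinement
  applies to internal vein midlines, while the outer contour keeps lattice
  (± simplification) accuracy.
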