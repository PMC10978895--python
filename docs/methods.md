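# Methods

This note documents the measurement model, the tunable parameters and
their defaults, the numerical choices made where the design was open, what
the synthetic validation shapes do and do not show about real scans, and
the known limitations.

## Normalization

All measurements are made on a normalized copy of the scan:

* **Orientation.** A user-supplied 3×3 rotation (e.g. exported from an
  external orientation workflow, as a 9-number JSON sidecar next to the
  mesh file) is applied verbatim. Otherwise principal axes of the vertex
  cloud are used: longest axis → y (length), second → x (width), shortest
  → z (thickness), with the y sign chosen so the narrower half (smaller
  mean plan half-width — the tip of a teardrop plan) points to +y.
  Eigenvector signs are canonicalized so repeated orientation is
  idempotent. Near-isotropic meshes (consecutive principal-value ratios
  below 1.01) are still oriented but flagged ambiguous.
* **Scale.** Isotropic rescale to length (y extent) = 1. All lengths
  below are in these dimensionless length units; all angles in degrees.
* **Resolution.** Resample to `target_vertices` (default 50,000); sparser
  meshes read systematically blunter, so a common density is enforced in
  both directions. Upsampling is midpoint subdivision (exactly
  surface-preserving). Downsampling is pass-wise greedy quadric-error
  edge collapse with *subset placement* (a collapse moves a vertex onto a
  surviving neighbor, so every output vertex lies exactly on the scanned
  surface). Two guards matter for edged objects: collapses creating
  flipped or low-quality triangles are vetoed (slivers would later punch
  holes in the alpha complex), and *feature vertices* — where an incident
  face normal deviates more than 12° from the mean vertex normal, i.e.
  ridge and rim vertices — are never removed, so the sampling density of
  the very edge being measured is preserved. Surface area is preserved to
  well under 1% at realistic densities.

## Outline detection

The perimeter is the boundary of the alpha shape of the vertices projected
to the plan (x–y) plane, computed from the 2D Delaunay triangulation:
triangles with effective radius ≤ α form the alpha complex; edges
belonging to exactly one such triangle form the boundary. The effective
radius is the circumradius *capped at the triangle's longest edge* —
near-degenerate slivers (a scanned vertical wall projecting onto its own
rim) otherwise have unbounded circumradius and leave permanent holes.
α defaults to the smallest value on a geometric grid (factor 1.3 steps up
from the mean projected nearest-neighbor spacing) that produces a single
simple loop enclosing every projected point; it can be fixed explicitly.

Boundary coordinates keep the z of their source vertices. Over blunt
stretches the projection is ill-posed — a near-vertical surface stacks
many vertices at the same plan position and the lifted z jitters across
the wall height — so a correction pass examines, per outline coordinate,
the mean inclination of the nearest `blunt_face_k` = 30 faces: where the
normals lie within `parallel_threshold_deg` = 15° of the plan plane, the
coordinate is flagged blunt and its z replaced by the mean z of the
nearest `blunt_k` = 50 vertices. Both neighborhoods are taken by
*plan-view* distance: a vertical prism samples the wall over its full
height, whereas a 3D ball centered on the provisional (wrong) z sees only
one end of it. The 15° window flags genuinely wall-like surfaces but not
steep-yet-sharp edges (a 145° edge has faces at 72.5°, outside a 75°
cutoff); x and y are never altered. Finally the outline is resampled to
`outline_points` = 1000 coordinates at uniform 3D arc-length spacing by
linear interpolation, starting at the tip (maximum y) and running
counter-clockwise in plan.

## Continuous edge-angle measurement

Vertices are assigned to the two faces by z against the nearest outline
coordinate (plan-view nearest); vertices within 1e-3 of the outline z are
labeled boundary and excluded (their direction vectors are near-zero).
Each remaining vertex `v` is paired with the opposing-face vertex `o`
nearest in plan view and with `e`, the closest point on the outline
*polyline* in 3D. The per-vertex angle is
`atan2(|(v−e)×(o−e)|, (v−e)·(o−e))`. Using the continuous foot for `e`
matters: the nearest of 1000 discrete coordinates is displaced along the
edge by up to half the coordinate spacing, which adds a common along-edge
component to both vectors and systematically shrinks the angle (measured:
−0.3° on the octahedron).

Only the outer band of the surface contributes: vertices ranked by 3D
distance to the outline are included, nearest first, until the faces fully
inside the included set reach `band_fraction` = 0.20 of total surface
area. The per-coordinate profile value is the mode of a Gaussian KDE over
the angles of the `knn_profile` = 50 nearest band vertices (Silverman
bandwidth floored at `kde_bw_floor_deg` = 0.5°, evaluated on a 0.1° grid
over 0–180°, ties toward the lower angle; fewer than 5 usable vertices
fall back to the median). The mode, unlike a mean, entirely ignores a
minority of outliers — the near-180° values that post-depositional
rounding and scanner limits produce at the very edge.

`k` and the bandwidth floor were calibrated once on the analytic shape
family and then frozen. The relevant physics: a vertex at arc depth `s`
from the rim of a curved edge measures a chord angle low by ≈ `s/R` per
face, so the neighborhood radius (set by `k` at the standard density)
bounds the attainable accuracy on curved edges. At 50,000 vertices,
k = 50 keeps the samples within roughly two mesh rings of the rim and the
profile within ~1.5° of closed-form lens angles across edge angles
52–145°; k = 100 doubles the depth and the bias. On planar-faced solids
(the octahedron) there is no such bias at any k. `band_convergence`
reproduces the plateau diagnostic: the profile mean is flat in the band
fraction above ~10%, confirming the 20% default is not load-bearing.

## Edge segmentation

The 1000-point profile, opened at the tip, is treated as a linear
signal. For each K = 0..`kmax` (10) the placement of K change points
minimizing the total squared deviation from segment means, with segments
of at least `min_seg` = 25 coordinates, is found exactly by dynamic
programming over suffixes (cost of any interval in O(1) via prefix sums;
equal-cost optima resolve to the lexicographically smallest breakpoint
set). The residual curve r(K) is non-increasing by construction.

K is selected at the elbow of the residual-error gradient: with per-point
drops `g(K) = r(K−1) − r(K)`, the chosen K maximizes `g(K)/g(K+1)` — the
sharpest kink of the gradient plot, i.e. the last change point whose
contribution dwarfs the next one's. (A chord-distance elbow on r itself
was tried and rejected: when true mean shifts differ in size, one dominant
drop makes later real drops look chord-flat, and K is systematically
underestimated.) Two floor rules return K = 0: a negligible total
residual, and a total relative drop below `elbow_min_drop` = 0.15.
The floor is calibrated to the method's own null: optimally placed change
points absorb up to ~6% of the residual of white noise and up to ~13% of
the spatially correlated sub-degree wiggle that KDE-mode quantization
leaves in a genuinely constant-angle profile, while any real edge contrast
of ≥ 2° drops the residual by ≥ 90%. Profiles are circular but segmented
linearly (as plotted); first and last segments with means within 5° are
flagged as likely halves of one edge spanning the start point, not merged.

## Segment measurements

* **Length**: sum of consecutive 3D gaps; segment lengths partition the
  perimeter exactly.
* **Sharpness**: a segment is sharp iff its mean angle is strictly below
  `sharp_threshold_deg` = 120 (a mean exactly at the threshold is blunt).
  The default is kept fixed for cross-assemblage comparability;
  `sharp_threshold` additionally derives a data-driven threshold from the
  pooled segment means of an assemblage — the density minimum between the
  two highest KDE peaks at least 15° apart (Silverman bandwidth floored at
  2°), reported both raw and floored to the nearest multiple of 10, with a
  unimodal fallback to 120. At least 30 pooled values are required.
* **Transverse asymmetry**: at each band vertex the edge angle is split by
  the horizontal unit vector from the outline foot toward the plan-view
  centroid of the outline polygon; the ratio min/max of the two
  half-angles (vertex side vs opposing side) is aggregated per outline
  coordinate by the same k-nearest KDE-mode estimator on a 0–1 grid
  (step 0.001, bandwidth floor 0.01). The plan centroid is one constant
  point per artifact; a per-cross-section center would be a plausible
  alternative but is harder to make robust on concave plans.
* **Surface concavity**: per vertex, the farthest `concavity_outer_m` = 20
  of the `concavity_k` = 60 nearest neighbors vote on the sign of the
  projection of the normal difference onto the unit separation direction:
  positive (normals tilting apart) = convex, negative = concave, within
  `planar_eps` = 5e-3 = planar; the score is (convex + planar/2)/m. The
  unit-direction projection makes the statistic exactly invariant under
  uniform scaling; `planar_eps` is then a normal-angle tolerance,
  calibrated so a 2° cone reads planar and a shallow (radius 2.5) bowl
  reads concave at standard density. Per-face profiles aggregate the
  per-vertex scores over each face's band vertices by KDE mode; category
  cutoffs 0.4/0.6 split concave/planar/convex, and the pair label is
  sorted ("concave-planar", never "planar-concave"). Segment-level
  asymmetry and concavity are means of the per-coordinate profiles over
  the segment.
* **Refinement**: width/thickness = x extent / z extent (scale-free).

## Synthetic validation shapes

The generators in `lithedge.shapes` provide every pipeline stage with
closed-form truth: the octahedron's equatorial dihedral (arccos(−1/3),
preserved exactly by midpoint subdivision without reprojection); lens
half-angles `arcsin(a/R)` per cap (validated against numeric surface
tangents to 1e-4 before any pipeline code is trusted); a blunt band of
known arc fraction blended with a 0.5%-perimeter linear taper (excluded
from oracle comparisons); a near-flat (2° cone) top for maximal asymmetry
and a planar face — an exactly horizontal plane would coincide with the
rim plane and be excluded by the boundary tolerance; a dished top behind
a short wall for concave-face aggregation; a closed cylinder (fully
blunt); and seeded piecewise-constant signals. All generators are
deterministic given parameters and seed; wall vertices get a tiny seeded
radial jitter so their projections are not exact duplicates, as in a real
scan.

What these shapes do **not** emulate: flake scars (real profiles carry
quasi-periodic scar-scale structure, not white noise), surface texture and
scanner noise, cortex, non-convex plan outlines, and non-watertight
scans. Passing the synthetic suite therefore demonstrates the geometry of
the measurement chain, not robustness to every artifact of real data; the
free constants most exposed to real-data character (α selection, the
blunt-parallelism window, k, the elbow floor) are all in `RunConfig`.

A geometric caveat discovered during design: a surface that is concave
toward the outside cannot border a plan-extreme outline from above — any
concave-up surface lies below its own rim. Near-edge concavity therefore
always reflects whatever surface physically borders the edge (on the
dished-top generator, its connecting wall); genuinely concave faces read
concave a short distance in from the edge.

## Degenerate inputs and numerical choices

Duplicate vertices are merged, zero-area and duplicate faces dropped, and
only the largest connected component kept at load time; meshes with fewer
than 4 vertices or no valid faces are rejected. Collinear plan
projections, self-intersecting outlines, and an empty face after
assignment (orientation failure) raise geometry errors. KDE grids are
scanned in increasing order so argmax ties resolve toward the lower
value; DP ties resolve toward earlier breakpoints; batch runs skip and log
per-file failures rather than aborting.

## Problem sizes

Tests and examples run the full pipeline at the standard 50,000-vertex
resolution for the quantitative recovery checks and at 6,000–20,000
vertices for structural checks where the contract does not depend on
density. The change-point dynamic program is exercised against exhaustive
enumeration on 100 seeded signals of length ≤ 30 (K ≤ 3), and elbow
selection on 100 seeded 1000-point profiles with true K ∈ 0..5.

## Known limitations

* The principal-axes orientation is a deterministic substitute for manual
  or tool-specific positioning; strongly curved or near-symmetric pieces
  may orient differently from an analyst's choice (use the rotation
  sidecar for exact reproduction of an external pose).
* Profile accuracy on curved edges is resolution-limited (chord bias
  ≈ neighborhood depth / edge radius, ~1–1.5° at the defaults); planar
  edge facets carry no such bias.
* The outline must be a single closed loop: holes, deep plan concavities
  at the alpha scale, or non-watertight scans beyond largest-component
  cleanup are out of scope.
* Segment means near the sharp/blunt threshold flip label with small
  profile changes; the pooled-distribution trough is the better instrument
  at assemblage scale.
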