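# Methods

## The vein-structure model

An implant's abutted-surface skeleton is a rooted tree of graded veins:
one *main* vein (the plate or region centre line), *lateral* veins
branching from it, and *minor* veins branching from laterals.  Vein growth
runs from higher to equal-or-lower grade; equal-grade continuations are
allowed because both the L-plate head (the opposite head vein continues the
branch lateral collinearly) and the clover branch extensions are
lateral-to-lateral edges.  Skeletons are planar and strictly trees: every
non-root point has exactly one incoming vein.

Each vein carries a direction code `γ ∈ [0, 2)` (0 = +x, +0.5 per
counter-clockwise quarter turn; planar angle = `180 γ` degrees) and a
length in mm.  A single rule converts an interior branching angle `α`
(degrees, measured between the parent vein and the child) into the child's
code: a left child points `180 − α` degrees counter-clockwise of its
parent's direction, a right child the same amount clockwise.  For a
vertical main vein this reduces to the three-branch head-angle relation
exposed as `alpha_to_gamma`; the branch enumeration makes the caller
disambiguate the right-lateral form at exactly 90°, where the obtuse and
acute formulas meet.

Quadrant labels for γ use open intervals; the four boundary codes
(0, 0.5, 1, 1.5) map to the axis labels RIGHT/UP/LEFT/DOWN so the mapping
is total.

## Canonical numbering and the adjacency pair

Vertices are numbered bottom-to-top and left-to-right, **subject to the
constraint that every vein starts at an already-numbered point**: a Kahn
traversal that always releases the ready vertex with the smallest
`(y, x, previous index)` key.  The parents-first constraint is not
cosmetic — tail laterals of the T- and L-plates are horizontal (their
endpoints share the root's height and one lies to its left), and branch
angles below 90° place lateral endpoints *below* their attachment point, so
a plain `(y, x)` sort would break the parent-before-child property.  With
the constrained order, the morphological matrix `M1` (γ codes) and
dimensional matrix `M2` (lengths) are strictly upper triangular for every
tree, by construction.

Since `γ = 0` is a legal direction while empty matrix entries are also
stored as zero, an explicit boolean edge mask travels with the matrices and
is the source of truth for which entries are veins.  This makes the
graph ↔ matrix codec lossless (verified by round-trip property tests on
random trees).

Layout realizes each child at `parent + v·(cos γπ, sin γπ)`.  Unit vectors
at the four axis codes are taken exactly (±1/0) rather than through
floating trig, so horizontal veins have exactly equal y and the left/right
tie-break behaves as intended.

## Templates

All four builders consume named semantic parameters — lengths in mm,
angles in degrees, validated to `length > 0` and `0 < angle ≤ 180` — and
return a laid-out, canonically numbered graph.

* **T-plate** (10 points, 9 veins; 11 semantic parameters + optional
  thickness `n1` and screw-hole diameter `d1`): vertical main vein `h1`,
  horizontal tail laterals `l1`/`m1`, head laterals `l2`/`m2` at angles
  `alpha1`/`alpha2`, and a perpendicular minor pair (`u1`,`t1` / `u2`,`t2`)
  at each head-lateral endpoint defining the head width.  The T-plate's
  relation set is enforced verbatim: `90 < α1,α2 < 180`, `u1 = t1`,
  `u2 = t2`, `l1 = m1`, `l1 < l2 < h1`, and `d1 < 2 t1` when `d1` is given.
* **L-plate, left** (8 points): T-like tail; the head has one lateral at a
  free direction code `gamma3` whose opposite vein continues collinearly
  (`γ + 1 mod 2`), with one perpendicular minor pair on the branch side.
  The right plate is the mirror image across the main vein
  (`x → −x`, `γ → (1 − γ) mod 2`).
* **Clover head** (19 points, 32 parameters): two-segment main vein
  (`h3`, `h4`); branch laterals `l5@α4` / `m5@α5` at the bottom; adjuster
  pairs `l6@α6`/`m6@α7` at the centre and `l7@α8`/`m7@α9` at the top;
  collinear extensions `l8`/`m8` of the branch laterals (no angle, like the
  L-plate head); and four minor pairs `u4..u7`/`t4..t7` at angles
  `α10..α17` on the branch-lateral and extension endpoints.  This
  allocation consumes exactly the 32 printed parameters and respects the
  left/right angle symmetry of the printed rows.  Only range checks apply —
  the printed rows themselves break `u = t` pairing, so stricter defaults
  would reject real data.
* **Femoral-stem region** (23 points, 18 parameters): three branching
  levels `i = 1..3` on a five-point main vein; at each level a left lateral
  `l_i@β_i` and right lateral `m_i@θ_i`, each with a minor vein (`u_i`,
  `t_i`) leaving the lateral's midpoint perpendicular to it on the forward
  (+y) side.  The printed tables carry no main-vein length, so the level
  spacing is a structural constant (30 mm, a typical stem-level pitch;
  overridable through the builder).

The two printed parameter tables ship as packaged CSVs (7 clover rows,
8 stem rows) and are the default fixtures of the tests and the demo
pipeline.

## Retrieval

Stored records cache the adjacency pair of their skeleton.  A query is
answered in three stages:

1. **Vertex count** — candidates must share the query template's matrix
   dimension.
2. **Morphology** — the γ codes of the two key laterals (T/L: head
   laterals; clover: bottom branch laterals; stem: the level-1 laterals)
   are compared.  Both discrepancies must satisfy `|δ| ≤ gamma_tol`
   (default 0.005).  Because γ scales as 180° per unit, 0.005 admits angle
   changes up to 0.9° and rejects 1.0° — "within one degree".
3. **Size** — `δ3` compares total main-vein lengths, relative to the query
   by default (`|δ3| ≤ 0.1`); an absolute-mm mode is available.  0.1 mm
   absolute on decimetre-scale plates would be far stricter than "roughly
   conforms", which is why relative is the default.

The winning candidate minimizes `|δ1| + |δ2|`, ties broken by `|δ3|`, then
by L1 proximity of the full matrix pair (two records can be identical in
their key laterals yet differ elsewhere — the stem table contains such a
pair), then by record id.  On a size miss the stored feature's main vein is
set to the query's and saved as a *new* record (stored records are never
mutated); with no shape match the query parameters are instantiated
directly.  Both paths insert into the database, so repeated queries
converge to exact matches.

## Geometry

The boundary sketch connects the skeleton's *leaf* endpoints with straight
segments in counter-clockwise angular order around the centroid of all
skeleton points; interior feature points stay interior.  An `end_cap`
parameter adds two pad points continuing the main-vein axis beyond the
root and the farthest point along it, so the tail and tip of the plate are
enclosed.  No fillets or arcs are generated; rounded outlines are
cosmetic and out of scope.  Self-intersecting traversals are reported as
errors, never silently repaired.

Filling uses shapely's constrained Delaunay triangulation (an exact
partition, so the triangulated area equals the polygon area to round-off;
a 0.5% guard is asserted anyway).  Triangles are oriented CCW and the
deterministic triangulation of a fixed input polygon makes repeated runs
byte-stable.  Extrusion builds a watertight prism (volume = area ×
thickness).  Screw holes are explicit inputs; a convenience helper spaces
`floor(h_main / 3 d1)` holes equally along the main vein, a neutral
default that avoids inventing clinical placement rules.  Holes are
subtracted from the base polygon as 64-gon rings *before* re-triangulation
and re-extrusion, so the solid stays exactly watertight and each hole
removes a faceted-cylinder volume within 0.17% of `π r² t`.  Export
formats: binary STL and OBJ via trimesh, SVG (mm user units) via a small
built-in serializer.

The extrusion is flat.  Real abutted surfaces are curved; curvature
handling is deliberately excluded — the fit metrics below operate on
arbitrary 3D point sets, which may come from any surface source.

## Fit assessment

Given pre-aligned plate and bone point sets (mm), the package computes
both directed Hausdorff distances with an exact KD-tree (brute force is
used only as an independent oracle in tests), the symmetric Hausdorff
distance (valid < 0.3 mm), and the average plate-to-bone nearest-neighbour
distance summarized by the fitting index `1/(1 + avg/2)`.  The index is a
stand-in with the right calibration — it maps `[0, ∞) → (0, 1]`, is
strictly decreasing, and equals 0.5 at exactly 2 mm average distance, the
published correspondence between "average below 2 mm" and "index above
0.5"; any other monotone map can be injected via `index_fn`.  A
corresponded variant scores paired point lists for protocols that select
matching feature points on both surfaces.  Registration/ICP is out of
scope; inputs are assumed aligned by the upstream design workflow.

## Synthetic data

No patient bone surface is distributed, so the generators stand in:

* `random_vein_tree(n, seed)` — random valid skeletons (root MAIN, depth-1
  LATERAL, deeper MINOR; γ uniform on [0, 2); lengths uniform on
  [5, 50] mm), used to exercise the codec and validators.
* `synthetic_bone_patch(spec)` — points on a cylinder section (default
  radius 20 mm, 60 × 30 mm patch — a long-bone diaphysis is approximately
  cylindrical at that scale) with optional Gaussian noise along the
  analytic normal.
* `offset_copy` — exact normal or +z offsets.  Because the cylinder is
  convex, a noiseless patch offset outward by `d` has every
  nearest-neighbour distance exactly `d`, giving the fit metrics a closed
  ground truth.

All generators are pure functions of their arguments (one named RNG per
call, no global state).  What passing tests on these fixtures shows is
that the metrics and pipelines behave correctly on surfaces with known
structure; they say nothing about anatomical realism — there is no
statistical shape model, no cortical irregularity, and published
patient-specific fit values cannot be reproduced without the underlying
patient data.  The thresholds (0.3 mm, index 0.5 at 2 mm, γ 0.005, size
0.1) are taken as given.

## Numerical choices

* Equality in parameter relations uses a 1e-9 relative tolerance; the
  graph round trip compares indices and masks exactly and weights to 1e-9
  (the codec copies values, it does not compute).
* Tie-breaks: canonical numbering `(y, x, previous index)`; retrieval as
  described above; hole facets fixed at 64 segments.
* Degenerate inputs raise typed errors (`DomainError`, `StructureError`,
  `GeometryError`, …) rather than warnings; `validate_graph` returns
  diagnostics instead of raising so callers can collect all violations.
* Problem sizes in the test-suite property sweeps: 100 random trees of
  3–25 points for the codec, 200 random point-set pairs (≤ 40 points each)
  for the Hausdorff oracle, 1500–2000-point bone patches for fit
  calibration — small enough to run the whole suite in seconds while
  covering every code path.

## Known limitations

* Skeletons are planar trees; multi-parent DAGs and 3D skeletons are
  rejected by validation.
* Boundary construction by angular sort assumes a star-shaped leaf
  arrangement around the centroid; extremely concave custom topologies can
  produce a reported (not repaired) self-intersection.
* The stem template's level spacing is structural, not semantic, so size
  retrieval between stem records relies on the whole-matrix proximity
  tie-break rather than a main-vein length difference.
* Flat extrusion only; no NURBS/B-rep, fillets, chamfers, countersinks, or
  finite-element analysis.
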