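# Methods

This note records the models and procedures the package implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic benchmark does and does not show.

## Coordinate conventions

Right-handed frame, z up, all lengths in centimetres, angles in degrees.
Typical scene scale: trees 150–190 cm tall, branch radii 0.8–4 cm,
sensor-scale noise of a few millimetres.

## Preprocessing

Cropping keeps points inside an axis-aligned box and/or within a radial
distance of the origin (both offered because a capture may be bounded
either way). Statistical Outlier Removal computes, per point, the mean
Euclidean distance *d_i* to its *k* nearest neighbors (the query point
excluded, neighbor ties broken by index) and removes the point iff

    d_i > mu + lambda * sigma,

where *mu*, *sigma* are the mean and standard deviation of {*d_i*} over
the whole cloud. *lambda* is a standard-deviation multiplier — smaller
values remove more — with useful range roughly [0, 1]; the defaults are
*k* = 40, *lambda* = 0.2. The rule is deliberately the textbook SOR
construction; note it is not idempotent (a second pass can remove more),
but the removed set is monotone in *lambda* at fixed *k*, which the suite
verifies.

## Two-view registration

Each side of the tree is captured separately; the two views are related
by roughly a half-turn about the vertical axis. Direct ICP from such a
distant start is unreliable, so registration is two-stage:

1. **Marker initialization.** Three spherical target balls are visible
   in both views. Their centers come from an algebraic least-squares
   sphere fit (the linearized |x−c|² = r² system); correspondence
   between the two center triples is fixed by triangle congruence, each
   vertex keyed by the length of its opposite side. A near-equilateral
   marker layout (side spread < 2·tol) is rejected as ambiguous — the
   markers should be placed with clearly unequal spacing. The rigid
   motion then comes from the SVD orthogonal Procrustes solution with a
   reflection guard.
2. **ICP refinement.** Point-to-point ICP in which a candidate pair
   must pass all of: distance ≤ `max_correspondence` (5 cm), surface
   variation difference ≤ `curvature_tol` (0.05 on the [0, 1/3] scale,
   with curvature from the eigenvalues of the k = 20 neighborhood
   covariance), **reciprocity** (the pair must be mutual nearest
   neighbors), and a distance **trim** (closest 50 % of surviving pairs).
   Iteration stops when the RMSE improves by less than 1e-6 cm, after 50
   iterations, or when a step fails to improve the RMSE (the step is
   rejected, so the reported RMSE trace is non-increasing).

The reciprocity and trimming gates deserve explanation. Opposing views
see complementary halves of every branch cylinder. Under plain
nearest-neighbor pairing, back-surface points lock onto front-surface
points roughly one branch diameter away, and ICP converges confidently
to a translation biased by ~1.5 cm — worse than its initialization.
Reciprocity rejects exactly those pairs (the front point's own nearest
neighbor is a genuinely shared point, not the back point), and trimming
concentrates the solve on the overlap. Both are standard ICP variants
(one-to-one rejection, trimmed ICP). With three well-separated markers
the initialization alone is accurate to ~0.1 cm; refinement then reaches
~0.05 cm on the synthetic benchmark.

`registration_error` reports the RMS nearest-neighbor distance from the
transformed back view to the front view over pairs within a gate. At
the default 5 cm gate this metric mixes true misalignment with
view-coverage mismatch (back-only surfaces matching front surfaces a
branch diameter away even under a perfect transform); for a noise-floor
comparison use a gate of a few multiples of the sensor noise.

## Space colonization skeletonization

The cloud's points act as attractions; a rooted skeleton grows from a
seed by iterating:

1. every attraction strictly within *R* of its nearest skeleton node
   joins that node's influence set *S(p)* (one node per attraction;
   nearest-node ties go to the lower node id);
2. each influenced node computes *V_p*, the normalized sum of unit
   vectors from the node **toward** its attractions;
3. attractions outside the inclusive sector of half-angle *theta* about
   *V_p* are set aside for this node this iteration;
4. the growth direction *f* is the normalized sum of unit vectors toward
   the sector attractions; the child is placed at *p + Ds·f* (one child
   per influenced node per iteration; a child duplicating an existing
   node position within 1e-6 cm is skipped);
5. attractions within *Rd* (inclusive) of any new node are consumed.

Defaults: *R* = 8.2, *theta* = 22.5°, *Ds* = 4.0, *Rd* = 6.0 cm. The
loop ends when no attraction influences any node, after `max_iterations`
(500), or after `stall_limit` (10) consecutive iterations with no spawn
and no kill — the stall guard guarantees termination when isolated
attraction clusters remain out of reach.

Two degenerate cases are resolved deterministically. If the unit-vector
sum cancels exactly (symmetric surroundings), the node skips the
iteration — no random jitter. If the influence set is non-empty but the
sector is empty, the node grows one step along *V_p* itself. The second
case is essential, not cosmetic: at a bifurcation the frontier node's
*V_p* points between the two arms and the sector can be empty even
though plenty of attractions remain; without the fallback that node
holds both arms' attractions forever and whole subtrees are never
skeletonized. Growing along *V_p* lets the next node's Voronoi split
separate the arms. The same fallback makes thick branches workable:
on a cylindrical shell of radius *r* > *R*·tan *theta* (≈ 3.4 cm at the
defaults) no surface point falls in the sector of an interior node, and
the skeleton climbs the axis on *V_p* steps alone.

The default seed is the x–y centroid of the lowest 2 cm slab of the
cloud, dropped to the slab floor. Placing it at the floor (rather than
mid-slab) matters on surface clouds: the base ring of trunk points is
then azimuthally symmetric around the seed, *V_p* points straight up,
and the chain starts along the trunk axis.

The skeleton is exactly a rooted tree (each node spawned with one
parent), every edge has length *Ds*, and the attraction set shrinks
monotonically. A direct-loop reference implementation (no spatial
index) reproduces the optimized colonizer node-for-node on small
instances; the suite enforces this.

A sign remark: direction sums use vectors from the skeleton node toward
the attraction points, which is what makes growth advance into
unclaimed space. The opposite orientation is available as
`legacy_sign` for comparison; it is not useful for skeletonization.

## Branch labeling and pruning points

The skeleton's parent→child links form a directed graph. The **trunk**
is traced greedily from the root (the lowest vertex): the first edge is
the root's most vertical out-edge; thereafter the successor edge with
the smallest turn angle *psi* relative to the previous accepted edge is
taken, stopping when even the best successor turns by more than
`psi_max`. The check applies to sole successors too, so the trunk also
terminates where an unbranched chain bends sharply into a scaffold.
`psi_max` defaults to 30°: comfortably above the per-edge jitter of a
colonized chain (node positions wobble ~1 cm at 4 cm spacing, i.e.
turns of ~15–25°) and below the 35–50° take-off of open-center
scaffolds. Ties anywhere break toward the smaller child id, making the
result independent of child-list order.

**Branch origins** are trunk vertices with at least one off-trunk
successor, plus the trunk top. For each origin and each off-trunk child
subtree, depth-first search reaches every endpoint, paths are
backtracked to the origin, and the path with the greatest cumulative
Euclidean length *L_i* is the primary-branch candidate of that subtree
(so the trunk top can yield two primaries while inner junctions
typically yield one). Candidates with *L_i* < `min_branch_length`
(50 cm, inclusive with a 1e-9 float guard) are rejected as false
branches — short necrotic stubs or junction artifacts — and every edge
that is neither trunk nor primary is lateral. The three classes
partition the edge set exactly.

The **pruning point** of each primary branch lies at arc length
`prune_fraction`·*L_i* (default 2/3) from the branch origin, found by
walking the path and interpolating linearly on the edge where the
cumulative length crosses the target. Arc length, not chord: *L_i* is
defined as a sum of per-edge Euclidean distances. The adaptive 2/3 rule
(rather than a fixed cut length) also keeps the cut inside the
skeleton's most reliable region, away from dense lateral bifurcations.

## Pruned-tree modeling

Each cut inserts a vertex at the pruning position and deletes the distal
vertex of the host edge with its entire subtree, so exactly the distal
third of each primary branch (by arc length) is removed. Radii follow
the pipe model from a measured root radius (default 4.1 cm): along
unbranched runs the radius carries unchanged; at a junction with child
subtree weights *w_i* (total subtree edge length, a proxy for supported
biomass — the pipe model constrains only the sum over children, not the
split, so the split rule is our choice),

    r_child_i = r_parent * (w_i / sum_j w_j)^(1/n),   n = 2,

which conserves cross-sectional area exactly at every junction and makes
radii non-increasing from root to leaf. Leaf radii are floored at
`min_tip_radius` (0.2 cm, logged when applied) so deep trees do not
taper to zero. The mesh is one capped conical frustum per edge (16
sides), base and top radii from the edge's endpoints; per-segment the
mesh is watertight, and the inscribed-polygon error is bounded by the
sagitta 2r·sin²(π/2s).

## The synthetic benchmark

`generate_tree` builds vase-form ground truth: a short vertical trunk
(45 cm) of piecewise-linear segments (4 cm) with mild curvature; 3–4
scaffolds, two splitting from the trunk top and the rest attached along
the upper trunk, taking off at 40–55° elevation with roughly even
azimuths; 1–3 laterals per scaffold. The tallest scaffold fixes the
total height (default target 170 cm; configured draws stay in the
150–190 cm band). True pruning points are placed at exactly 2/3 of each
scaffold's arc length. Clouds are sampled on cylinder surfaces (trunk
2.5, primary 1.5, lateral 0.8 cm — a pipe-model-consistent taper, all
below the *R*·tan *theta* ≈ 3.4 cm regime where axis-mode colonization
is reliable) at 1.5 points/cm² with radial Gaussian noise (σ = 0.15 cm,
sensor-plus-registration scale) and 2 % uniform box outliers. Two-view
scenes keep a point when its outward normal faces the camera or with
10 % see-through probability, add three sphere markers (3.5 cm radius)
at fixed non-equilateral world positions, and express the back view in
its own frame via the known rigid motion.

What passing tests show — and do not. The generator's clouds are
surfaces of clean cylinders with isotropic noise; real depth-camera
captures have view-dependent density, quantization, mixed pixels,
clutter, and unmodeled occlusion from twigs. Skeleton fidelity (mean
node-to-centerline distance ≤ *Ds*; the mean, because bifurcation
regions transiently deviate before recovering) and exact transform
recovery on the benchmark therefore bound the method's behavior under
idealized geometry, not field performance. Field-scale registration
error on real orchard trees is reported elsewhere at ~0.7 cm and is not
reproducible here. Because the two views are subsets of one sampled
cloud, genuinely shared points coincide exactly; this makes transform
recovery on the benchmark easier than on independently sampled scans.

Branch-count recovery on colonized skeletons is deliberately not an
acceptance property: near the trunk top the greedy trunk trace can stop
an edge or two early or absorb an unusually vertical scaffold, merging
or splitting one primary — the same failure mode the 50 cm false-branch
filter exists to mitigate. The per-edge labeling accuracy test runs on
exact ground-truth skeletons, isolating the graph analysis from
colonization noise.

## Known limitations

- Search radius and deletion threshold are global; dense lateral regions
  would benefit from locally adapted radii.
- Primary-branch selection uses length alone; a branch leaving a
  junction at an implausible angle but with the greatest length still
  wins (a weighted length-plus-angle score is a known extension, not
  implemented).
- No skeleton re-centering or smoothing: node positions inherit the
  attraction distribution's jitter (~1 cm at the default density).
- Radii are allocated top-down from one measured root radius; nothing is
  estimated from the cloud itself.
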