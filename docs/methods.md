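# Methods

This note records the model implemented by `fibregrow`, the choices made
where the procedure was genuinely open, the numerical conventions, and
the limits of what the synthetic tests demonstrate.

## Geometry and units

All coordinates are micrometres in a right-handed frame with the growth
region the box `[0, L]^3` and the primary bundle axis along z. A grown
fibre is a skeleton — an ordered list of points with per-point realized
radii — whose geometric body is the chain of capsules swept along the
segments with linearly interpolated radii. Signed distances to that body
use the closest-parameter approximation (radius evaluated at the closest
point of the segment), exact for constant radii and accurate to
O(|r1 − r0|) otherwise, far below the skeleton spacing.

## Initialisation

* **Radii.** Gamma-distributed with shape `mu_r^2/sigma_r^2` and scale
  `sigma_r^2/mu_r` — the standard positive-support choice for axon-radius
  phantoms; `sigma_r = 0` degenerates to a constant. Radii are consumed in
  sample order (not sorted) so the packed subset keeps the target
  distribution.
* **Entry-face packing.** Random placement followed by pairwise-repulsion
  relaxation with an event-driven inflation schedule: overlaps are
  resolved at a growing radius scale (0.5 → 1.0) before the scale
  advances, which settles the configuration toward a jammed state and
  reaches 75% areal density on a 20×20 µm face in a few seconds. A
  microscopic residual overlap at convergence is cleared by shrinking all
  radii by that residual (relative cost ≤ 1e-4); if the relaxation stalls
  far from feasible, the most conflicted circle is dropped and a warning
  reports the achieved density.
* **Directions.** Watson sampling is exact rejection on
  `w = 1 − cos(theta)`: the density ∝ `exp(kappa(w² − 2w))` on [0, 1] is
  dominated by `exp(−kappa w)`, so proposals are Exp(kappa) truncated to
  [0, 1], accepted with probability `exp(kappa(w² − w))`. Acceptance stays
  O(1) at every concentration (a uniform proposal degrades as 1/(2kappa)
  and is unusable by kappa ~ 10^4). The ESAG sampler draws from the
  trivariate normal with `V^{-1} = I + (sqrt(1+|gamma|²) − 1)(xi1 xi1' +
  xi2 xi2') + gamma1(xi1 xi1' − xi2 xi2') + gamma2(xi1 xi2' + xi2 xi1')`
  (unit determinant, identity along mu) and normalises; `gamma = 0`
  reduces to the isotropic angular Gaussian.
* **Targets.** Each start point shoots its sampled direction through the
  region; the boundary exit is the target. Axial (Watson) draws are
  flipped into the inward hemisphere; directions with no inward component
  are resampled.
* **Node cloud.** Uniform over the region padded by `2 mu_r` per side so
  boundary fibres are not starved of candidate nodes; fibres themselves
  terminate on the true boundary.

## Growth

Nodes are Delaunay-connected (scipy/Qhull). Each node stores `d_c`, the
largest sustainable diameter there, defined as twice the shortest
distance to any existing fibre surface — a fibre centred on the node with
diameter `d_c` exactly touches its nearest neighbour. Updates are
min-only, so `d_c` never increases; nodes engulfed by a fibre are flagged
inaccessible rather than deleted. Clearances beyond 2.5 µm leave the
infinity sentinel ("no fibre nearby"); this bounds the update cost and
gives the bundle-affinity term a finite sensing range. The influence
radius is configurable per update.

**Step cost.** A fibre at head `s` scores each accessible, unvisited,
non-blacklisted neighbour `c` (with `d_c` above 10% of its target
diameter) as `l = l_t + f l_d`, `f = 0.2`. The direction term combines a
saturating step-length factor `|s−c|/(1+|s−c|)` with the misalignment
`1 − cos(angle(c−s, t−s))`. We combine them **additively** (halved, range
[0, 1.5)): misalignment is then penalised at every step length and the
committed greedy walk drifts to its target in near-straight paths. The
literal product composition is also implemented
(`direction_cost="product"`): it nullifies the angle penalty for short
steps, and on a fine node cloud the self-avoiding walk degenerates into a
space-filling wander (measured: ~600 µm of arc for 3.3 µm of net
displacement; parallel-bundle dispersion ~30°), which contradicts every
full-scale morphology this generator is meant to produce. The
additive default is therefore a deliberate correction, not an oversight.

**Completion.** The head completes when within the 90th-percentile
Delaunay edge length of the target or past the target's boundary-face
plane; the final point then snaps to the target, with its radius capped
by the actual clearance there. Ties in cost break to the lowest node
index; a fibre never revisits its own path; a step budget proportional to
the start-target distance guards against unbounded wander.

**Collapse.** A stuck fibre retreats along its own skeleton by
`g0 + k·delta` on attempt k (defaults 2 and 5 µm: retreats 2, 7, …, 27 µm
across the 5 escalations), blacklisting abandoned nodes; after the final
attempt it is removed. Removal is normal accounting, not an error.

**Dynamic network.** After each completed fibre, `N_added` nodes (default
2500) are placed uniformly in arc length along the path, offset radially
by 1.05–2.0 local radii in a uniformly random normal direction, and
clipped to the padded region. Re-triangulating 2×10^5 nodes after every
fibre costs ~12 s (measured) and scipy's incremental insertion is slower
still, so the insertion re-triangulates a local patch: the new nodes plus
existing nodes within the shell radius plus a two-node-spacing margin.
Nodes deep inside the patch receive exact local Delaunay neighbourhoods
(plus any old links leaving the patch); rim nodes keep their old links
and gain the patch links — a slightly superset graph that is harmless for
pathfinding. Small clouds (≤ 6×10^4 nodes) rebuild in full; both modes
are exposed.

**Fasciculation.** When the bundle that set a node's `d_c` is the growing
fibre's own, the shrinkage cost becomes `|(d0 − d_c)/d0|`, penalising
distance from the home bundle as well as crowding. With the corrected
direction cost this term measurably *tightens* same-bundle spacing (its
mechanistic purpose) but costs ~1 density point on an already-straight
parallel bundle, because hugging neighbours bends otherwise straight
lanes. In a step-cost regime where paths wander, the same term acts as a
guide rail and gains density; both regimes are reproducible with the
`direction_cost` switch.

## Global optimisation and radius recovery

After growth, every interior skeleton point is relaxed against its `n=10`
nearest points on other fibres: displacement `sum_j sgn(r_i + r_j −
|p_i − p_j|)(p_i − p_j)`, clamped to `0.2 r_i` per sweep, with `r_i` the
*target* radii `d0/2` (the desired spacing is the distance at which both
fibres could carry full diameter). Updates are synchronous (Jacobi) for
order-independence; sweeps stop at 200 or when the total-overlap metric
stops improving (relative tolerance 1e-4), and the best iterate is kept,
so the final overlap never exceeds the initial one. Endpoints never move;
radii and topology are untouched inside this step. Neighbour-count and
skeleton sampling matter: with skeleton spacing comparable to the radius
the distant same-fibre neighbours turn the net interaction attractive;
grown skeletons (spacing ≪ radius) are in the intended regime.

Density is regained by a separate radius-recovery pass: each point's
radius expands toward `d0/2`, limited by its distance to every other
fibre's surface (two Gauss–Seidel sweeps). Recovery is expansion-only —
the grown radius is a floor — because clearance queries at sub-node scale
are approximate and shrinking to them systematically deflates honest
radii; the phantom density is a voxel *union*, so residual surface-level
contact cannot inflate it, and the meshing stage resolves contact by
deformation. This pass is what converts the optimisation's freed space
into density (~+7 density points on the desk-scale parallel benchmark);
without a radius change the positional relaxation alone cannot alter the
volume a phantom occupies.

## Meshing

Each fibre is resampled at arc-length spacing `min(r)/2` into metaball
sources with the soft-object kernel `K(q) = (1 − q²)²`, `q = d/2r`
(compact support at twice the source radius). Two calibrations exist and
are both exact in their own regime: a single unit-amplitude source's
isosurface at `9/16` is a sphere of its nominal radius, and an
arc-length-weighted chain's isosurface at `16/15 (3/4)^{5/2}` (the
closed-form line integral of the kernel) is a cylinder of the nominal
radius. Fibre meshing uses the chain calibration; a meshed isolated
cylinder's equivalent diameter lands within 1% of nominal at the default
voxel (`min radius / 4`). Fibre tips are slightly blunted (half-chain
field), which matters only within ~one radius of the region boundary.

Each fibre's surface is extracted from its own field **minus the summed
fields of every other fibre**, so all fibres deform symmetrically away
from one another. The mutual construction makes the extracted regions
provably pairwise disjoint — a point in two regions would require
`−2 Σ(remaining fields) > 2·iso`, impossible for non-negative fields —
and opens a genuine gap at every contact that also absorbs
marching-cubes interpolation error. (A one-sided scheme, in which later
fibres deform around frozen earlier meshes, was implemented first and
measurably fails: metaball chains bulge beyond their nominal capsule at
bends, so a skeleton running close past a frozen mesh puts roughly twice
the isolevel of field on it and pierces it at grid precision.) Two
supporting passes keep skeleton geometry inside the scheme's safe zone:
a post-growth contact-resolution step moves interior skeleton points to
at least 0.6 of their radius outside every other fibre's surface, and
meshing drops end sources that run closer than half their radius past
another fibre (snapped tips retract instead of piercing). No smoothing
is applied after marching cubes (it would void the non-intersection
property). The non-intersection guarantee is verified, not assumed: an
exact Möller triangle–triangle intersection test (with bounding-sphere
pruning) over all mesh pairs is part of the test suite and the
acceptance script. Meshes are written as binary little-endian PLY with a
JSON manifest.

## Morphometry

* Centre lines: the mesh is rotated so its end-to-end vector lies along
  z; the area-weighted centroids of (default) 100 equidistant
  cross-sections are connected and rotated back. Empty slices interpolate
  from neighbours with a warning. For skeleton-level summaries the
  equivalent `skeleton_centreline` box-smooths the skeleton over one
  fibre diameter — the scale over which the implicit surface averages
  skeleton jitter — before resampling; phantom-level orientation
  statistics use these smoothed centre lines.
* Diameters: cross-section area perpendicular to each centre-line
  segment, reported as the equivalent-circle diameter `2 sqrt(A/pi)`; the
  component containing the centre line is used when a plane cuts the
  mesh more than once.
* Orientation histograms: directions (and their antipodes, so the
  histogram is exactly symmetric) are binned on an icosahedral sphere
  subdivided 3 times (1280 faces) by nearest face normal; densities are
  `count/(total × face solid angle)` in sr⁻¹ and integrate to 1. Face
  solid angles are averaged across antipodal pairs to remove round-off
  asymmetry.
* Density: voxel-centre occupancy against the capsule bodies (fast,
  union-based) or against meshes for small fixtures; default voxel
  0.2 µm.
* Virtual histology: mesh–plane section polygons rasterised to a
  labelled image (default 5 nm in-plane pixels). Shape metrics per axon:
  circularity `4πA/P²`, convexity `A/A_hull`, eccentricity from image
  second moments, and `A/(π r_max²)` with `r_max` the
  minimum-enclosing-circle radius (so a perfect disc scores 1). The
  perimeter is the traced contour simplified at one-pixel tolerance: a
  raw marching-squares contour overestimates a disc's perimeter by ~5%
  and the Crofton estimator underestimates a square's by ~5%, while the
  simplified contour recovers both closed forms within 1%. Axons touching
  the image edge, and single-pixel regions, are excluded.

## Study configurations and what the tests show

Desk-scale configurations keep the full pipeline inside interactive
budgets and are the sizes used throughout the tests and the acceptance
script, as this package's own reporting choice:

* reduced preset: 10 µm region, 2×10^5 nodes, target density 75% —
  ~99 fibres, ~5 minutes per phantom;
* ablation configuration: 6 µm region, 3×10^4 nodes, target 75%,
  1000 dynamic nodes per fibre, 3 seeds per arm;
* meshing benchmark: 5 µm region, ~25 fibres.

The full-fidelity preset (20 µm, 2.5×10^6 nodes) is retained for
fidelity runs and takes hours per phantom.

Measured at these scales: the reduced preset reaches ~62% density at
kappa=100 (target 75%) with output dispersion decreasing in kappa
(~21° at kappa=100 vs ~33° at kappa=8); output dispersion sits well above
the sampled target because node-to-node jitter adds to the intended
dispersion — at full scale the gap narrows but does not vanish. The
mechanism ablation at desk scale shows collapse and the dynamic network
as neutral (straight additive-cost growth rarely strands a parallel
fibre), global optimisation + radius recovery as the dominant gain
(~+7 points), and fasciculation as a ~1-point cost on parallel bundles;
on dispersed bundles the full mechanism set beats chemoattraction-only
growth by ~9 points. The strict "every mechanism individually helps"
ordering reported for the original wandering-growth regime does not hold
under the corrected direction cost, and the corresponding acceptance test
documents this honestly rather than masking it.

Synthetic phantoms here emulate axon-scale geometry (radius distribution,
dispersion, crossing, density) but not beading, undulation at sub-node
scales, myelin, or glial occupancy; passing tests demonstrate geometric
and statistical correctness of the generator and its measurements, not
biological completeness of the tissue model.

## Degenerate inputs and edge behaviour

`sigma_r = 0` gives constant radii; `n_added = 0` disables insertion;
a target density the packer cannot reach warns and proceeds with the best
packing; a fibre whose start is engulfed by existing fibres (possible in
crossing configurations, where entry faces are packed independently) is
removed at birth; an empty completed set warns and yields an empty
phantom; meshing a fibre annihilated by neighbouring negative fields
raises a per-fibre error that `mesh_phantom` collects without aborting
the rest.
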