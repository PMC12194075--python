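# Model and methods

`blastosim` simulates epithelial sheet bending — gastrulation by
invagination — with cells that are individually deformable, closed
triangulated surfaces.  This note records the model, its parameters and
defaults, the numerical choices, and what the bundled experiments do
and do not demonstrate.

## The cell

A cell is a subdivided-icosahedron mesh ("icosphere"): level 2 gives
162 vertices / 480 edges / 320 faces and is the default for desk-scale
experiments; level 3 gives the 642-vertex / 1280-face cell used for
full-size runs.  The subdivision inserts edge midpoints (merged by
exact parent-index pairs, so the surface is watertight by construction
and the vertex ordering is deterministic) and projects them to the
sphere.  All lengths are model units with the undeformed cell radius
as the natural scale 1; time is in model time units; forces are in the
units implied by mass 1 per vertex.

Positions on the cell surface are addressed by the **band coordinate**:
the polar angle θ from the apical pole expressed as a percentage,
100·θ/π.  A region like "20–65%" is the band whose polar angle lies
between 36° and 117°.  This is a fraction of polar *arc*, not of axial
height or of surface area; "0–50%" is exactly the apical hemisphere.
Band membership is assigned once on the undeformed sphere and then
travels with the vertices — a constricting region shrinks in area but
keeps its vertex set.  An edge belongs to a region only when both its
endpoints do, so no edge is ever half-constricted.

## Forces

**Cortical springs.**  Every edge is a nonlinear spring,

    F = −(k/l0)·x² − k·x,   x = l − l0,

negative F pulling the endpoints together.  The quadratic term makes
extension progressively harder than compression (strain stiffening of
cortical material); in compression the law softens and crosses zero at
l = 0, which is the physical boundary of the state space, so no clamp
is ever active in practice.  Default stiffness k = 0.5, the value used
by most of the bundled experiments; regional values (e.g. stiff apical
cap k = 1.5, soft basal side k = 0.1) are set by region bands and can
be ramped in time by stiffness events.

**Cortical strain.**  Rest lengths are globally factorised,
l0 = f_et·l_rest with f_et ∈ (0, 1], so the cortex is permanently
under tension against the conserved volume: the surface stays taut and
a free cell remains spherical.  Default f_et = 0.5.  The value is a
tension/smoothness trade-off: much smaller values put the springs deep
into the stiffening regime and demand a smaller time step; values near
1 leave the surface slack.

**Constriction.**  A constriction event multiplies the rest lengths of
a band by a factor f_c, ramped linearly from 1 over a configurable
duration (default 50 time units — "gradual" is a modelling requirement
to avoid shocks; the exact ramp shape is not critical in the
overdamped regime).  Constriction composes multiplicatively with
cortical strain (l0 = f_c·f_et·l_rest), so releasing it restores the
strained baseline.  When events overlap on an edge the one latest in
the schedule list wins, and the collision is logged.

**Volume conservation.**  Cell volume is computed exactly from the
closed mesh by the divergence theorem, V = (1/3) Σ x_i·n̂_i A_i.  The
restoring force has per-cell magnitude k_v·|V − V0|/V0 directed along
outward vertex normals when compressed and inward when inflated.  The
per-vertex magnitude is weighted by each vertex's share of the surface
area (normalised to cell-mean 1).  This weighting is deliberate: the
sum of area vectors over a closed surface is identically zero, so the
weighted force field is a true uniform pressure with exactly zero net
thrust on the cell.  An unweighted per-vertex force (available as
`weighting="uniform"` in `volume_force`) leaves a spurious net force
on any asymmetric cell, which shows up as a slow dt-dependent drift of
constricted cells — easily mistaken for physics.  Default k_v = 50,
chosen so the volume term dominates cortical tension and the relative
volume deviation of a strongly constricted cell stays well inside 1%.

**Adhesion.**  Vertices inside a cell's adhesive band may bond to
vertices of a neighbouring cell's band.  An unbonded adhesive vertex
is offered its nearest unbonded partner within the connect length
(default 0.3) and bonds with probability `adhesion_chance`% per
attempt; existing bonds are released with probability `break_chance`%
per step (letting the contact remodel) and immediately when stretched
past twice the connect length (a safety release that prevents detached
cells from staying tethered).  A vertex holds at most one bond.  The
bond force is constant, k_adh, pulling toward zero separation, with a
linear ramp below `lin_length` (default 0.05) to avoid on/off chatter
at contact; the two branches agree at the junction, so the law is
continuous and non-decreasing.  Defaults: adhesion_chance = 100,
break_chance = 0 (deterministic bonding — the stochastic machinery is
exercised through the chances when configured), k_adh = 0.5.  The pull
strength was calibrated together with the spacing (below) so that an
adhered sheet is cohesive enough to transfer constriction forces —
with weak bonds the plate behaves like loose beads and in-plate cells
shape exactly like detached ones.  Chances are interpreted per step;
per-unit-time semantics (scaled by Δt) can be selected in
configuration where step-rate independence matters.

**Collision.**  A contact is a vertex of one cell inside another
cell's boundary: the vertex's nearest surface feature is found by
exact point-triangle distances and the vertex counts as inside when it
lies behind the outward normal of its nearest face.  The response puts
k_col·depth (depth = perpendicular distance to the face plane;
k_col default 5) on the intruding vertex along the face normal, and the
opposite force on the face's three corners split by the foot point's
barycentric weights — the four vectors cancel exactly, and the pair of
cells deforms locally in proportion to their stiffnesses.  Cells do
not self-collide (the cortex model assumes moderate shapes); runs that
fold a single cortex onto itself are outside the validated regime.

**Confinement planes** (planar experiments) are immovable half-space
boundaries applying stiffness×depth restoring forces.

## Broad phase and cost

Each cell carries an axis-aligned bounding box.  Candidate pairs for
adhesion are those whose boxes inflated by the connect length overlap;
for collision the inflation is only the narrow-phase padding, which
keeps the tested vertex/face sets small.  Within a candidate pair only
elements inside the overlap region are examined.  Contacts are cached
as (vertex, face) pairs and re-evaluated against current positions
every step; the detection pass itself may run at a stride (scene
builders default to every 4th step for collision and every 5th for
bonds, logged in the manifest) — forces remain per-step, only the
discovery of *new* pairs is strided, which is accurate in the
overdamped regime where geometry changes slowly.  The resulting cost
is linear in cell count for shell-like packings, since each cell
overlaps a bounded number of neighbours.

## Dynamics

Newtonian point masses (m = 1 per vertex) under the damped Verlet
update

    x_{n+1} = (2 − c)·x_n − (1 − c)·x_{n−1} + a·Δt²,

with Δt = 0.05 and damping factor c = 0.2 by default; the first step
bootstraps from rest (x_{−1} = x_0).  Figure-style times ("T = 85",
"interval 100 time units") map to the simulation clock t = step·Δt;
the mapping and all parameters are echoed in the run manifest.  The
defaults put the system in the overdamped, quasi-static regime: the
trajectory is a sequence of near-equilibria, which is why halving Δt
leaves steady shapes unchanged (asserted in the tests).  The scheme is
exactly time-reversible at c = 0 and bounds energy error over long
runs, which the suite checks on a single spring.

The per-step loop: apply due schedule events → refresh bounding boxes,
bonds and contacts → accumulate forces (elastic + volume + adhesion +
collision + confinement) → integrate → record.  A non-finite force or
an inverted cell aborts the run with the offending module named and
the last state saved.  Runs are bit-reproducible given the seed; the
only RNG consumer is the adhesion bond machinery.

## Scenes

*Single cell* — one free icosphere.

*Detached plate* — a hexagonal-packing disc (counts 1, 7, 19, 37, 61,
91 for full discs; other counts, e.g. the 83-cell plate, trim the
outermost ring at evenly spaced angular positions — a deterministic
rule chosen here, since the original layout of such plates is not
derivable).  Apical axes point along +z; cells adhere apico-laterally
(20–65% band by default).

*Planar ring* — a cross-section through a blastula: cells on a circle
between two plates, apical axes radially outward, endodermal arc
selectable by count.

*Blastula* — n cells (32–1024) on a Fibonacci-spiral lattice on a
sphere whose radius is set so nearest neighbours sit `spacing_factor`
(default 2.05) cell radii apart; apical axes outward; the endodermal
plate is cut by a shape mask (cap, rectangle, triangle, T, five-lobed
star) around the oral pole in an azimuthal-equidistant chart.
Endoderm adheres at 20–65%, ectoderm at 20–100%.  The spiral placement
is a deterministic quasi-uniform rule valid for any n; it will not
reproduce cell-exact endoderm counts of any particular embryo, and no
such reproduction is claimed.

Plates are decomposed into concentric rings by breadth-first search
over the cell-adjacency graph (cells adjacent when their centers are
closer than 1.3× the mean nearest-neighbour distance) from the center
cell; constriction modes schedule the rings simultaneously, center
first, or edge first with a configurable interval.  Every built scene
passes mesh validity before step 0, and experiments begin with an
equilibration phase (events start at t ≈ 50) so neighbours bond before
anything constricts.

## Measurements

Cell metrics: volume, surface area, apico-basal height, maximal
lateral width, elongation (height/width), apical-band extents along
plate-frame directions, sphericity π^(1/3)(6V)^(2/3)/A.  Scene
metrics: bond count; invagination depth (inward displacement of the
plate-center cell in the scene frame, so rigid motions cancel); and
blastoporal opening diameter.  The opening rim is operationalised as
follows: in each azimuth bin around the oral axis take the vertex
highest along the axis, and read the diameter as twice the mean axis
distance of those rim vertices; if the surface still covers the oral
pole (near-axis vertices at near-maximal height) the shape is closed
and the opening is 0.  This rule reads 2R on a hemispherical cup and 0
on a sphere; it is a geometric stand-in for the visual rim and shares
its limitations on strongly folded rims.

## The canonical experiments and their protocol

`blastosim.experiments` fixes the study conditions used by the test
suite and by `scripts/acceptance.py`:

* *Single-cell volume run* — a level-3 cell constricts its apical
  hemisphere (0–50%, the band of the single-cell demonstrations) at
  f_c = 0.1; the relative volume deviation is recorded at every 20th
  step.
* *Free-cell sphericity* — a level-2 cell relaxed for 10⁴ steps.
* *Plate elongation* — 19-cell hex plates constricting the apical cap
  (0–30%).  The cap band is deliberately narrower than the single-cell
  demo band: constricting the whole upper hemisphere of plate cells
  folds their top halves into compact knots and the cells end squatter,
  not taller, which buries the confinement effect the experiment is
  about.  Plates are packed at 1.95 cell radii with collision constant
  10 and bond pull 0.5 — tight enough that neighbours genuinely block
  lateral expansion; with loose packing or weak bonds an "adhered"
  plate behaves like unconnected beads and in-plate cells shape exactly
  like detached ones.  Elongation is read at t = 400 (constriction ends
  at t = 70): the shapes are quasi-static there and the sheet still has
  plate geometry.  Far later a free plate slowly curls onto itself into
  the closed-oval end state and cell shapes become dominated by the
  enclosing fold — a different regime from the plate measurement.
* *Constriction-mode signatures* — 37-cell plates, ring interval 100.
  Ring-resolved displacement along the apical axis is read in the early
  window: at t = 120 (one interval after the start) for the
  center-first dip and the simultaneous edge response, and at t = 200
  for the edge-first center bulge (still before the center ring's own
  constriction at t = 320).
* *Planar invagination* — a 32-cell ring with an 8-cell endodermal arc
  between two plates, run to t = 800.  The bond pull is raised to 2.0
  here: in a single-cell-thick ring each cell passes the apical
  contraction to exactly two lateral neighbours, whereas a sheet
  spreads it over six, so the per-bond force must carry more.

These parameter choices are calibration of the model's free constants,
made once from the mechanics above; they are echoed into every run
manifest.

## What the experiments show — and what they do not

The bundled desk-scale experiments use level-2 cells and 19–37-cell
plates or ≤ 64-cell shells, with run lengths of a few hundred time
units; these sizes were chosen so the full suite of qualitative checks
(volume conservation under constriction, free-cell sphericity,
in-plate vs detached elongation, constriction-factor monotonicity,
constriction-mode signatures, planar invagination) completes quickly
on one core.  Full-size scripts (256–1024 cells, level-3 meshes) are
provided under `scripts/experiments/` with their expected qualitative
outcomes (bowl-shaped gastrula, wide blastoporal opening) documented
there; they are not asserted by the test suite.

The simulated material is a single-layer spring cortex with implicit
cytoplasm: no viscoelastic rheology, no bending stiffness, no active
fluctuations, no cell division or rearrangement, no filopodial
zippering.  Conclusions supported by this package are therefore about
the sufficiency of constriction + adhesion + volume conservation for
sheet bending and about orderings/signatures among scenarios — not
about absolute developmental timescales or about mechanisms the model
omits.

## Known limitations

* The inside/outside test uses the nearest-face normal; for extremely
  non-convex, deeply interpenetrating cells it can misclassify — the
  collision response prevents such states from developing in the
  validated regime.
* Adhesion partner choice is nearest-first with index tie-breaks;
  multi-partner bonds are not modelled.
* The blastoporal rim rule can underestimate strongly folded openings.
* Detection strides trade a small detection latency for speed; set
  both strides to 1 to recover per-step detection exactly.
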