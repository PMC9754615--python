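# Methods

## Membrane representation

The membrane is a closed, consistently oriented 2-manifold triangle mesh
(`TriMesh`): vertex positions in units of l̄ = 1000 nm, faces ordered by the
right-hand rule with outward normals, and a per-vertex normalized lipid
density ρ (initially 1).  Closedness (every edge shared by exactly two
faces, Euler characteristic 2), orientation consistency, positive density
and valence bounds are checked by `validate_mesh`; every remeshing
operation re-validates the mesh it produces.

Discrete geometry follows the cotangent scheme: the mean-curvature operator
K(i) = (1/2A_v) Σ_j (cot θ_ij + cot φ_ij)(r_i − r_j) with the mixed vertex
area A_v (exact Voronoi split for non-obtuse triangles, area/2–area/4
clamps for obtuse ones, so the A_v tile the surface to machine precision).
Enclosed volume is the signed-tetrahedron sum Σ det(r1, r2, r3)/6.
Cotangents are clamped to |cot| ≤ 1e8 so near-degenerate triangles occurring
transiently during relaxation do not produce infinities; `validate_mesh`
still reports exact degeneracy.

On a convex mesh K points along the outward normal (it equals twice the
area gradient); only |K| enters the energy, and sign-sensitive analyses dot
K with the outward normal explicitly.

## Free-energy terms

All parameters default to the study's values in natural units
(Ē = 10 k_BT, l̄ = 1000 nm, s̄ = 1 s): κ = 1 Ē, C0 = 0, μ = 100 l̄²/(Ē s̄),
l0 = 1 l̄, V0 = 0.2 Ē, b = 0.5, r11…r22 = 0.05/0.75/1.25/1.75 l̄,
k11…k22 = 50/25/25/50 l̄⁻¹, k_w = 100 l̄⁻¹, l_min = −0.05 l̄, l_max = 2.2 l̄,
dl = 1e-4 l̄, BCE thresholds 0.1/0.7/1.3/1.7 l̄, k_v = 4 Ē l̄⁻³,
k_s = 8 Ē l̄⁻², k_s' = 12 Ē l̄⁻³, k_d ∈ [0.025, 0.25] s̄⁻¹, k_BT = 0.1 Ē.

**Internal potential.**  The published closed form of V_in is typographically
inconsistent (as printed, its "barrier" terms are unbounded wells and its
"walls" are bounded steps, contradicting the stated wall singularity at
l_max).  The implementation reconstructs the intended shape: each barrier is
a bump of relative height `b` built from two opposed logistic sigmoids on
[r11, r12] and [r21, r22], and the walls are coth terms singular at l_min
and l_max.  A constant offset V′, computed once per parameter set as minus
the grid minimum, makes min V_in = 0 hold exactly on the sampling grid.
The resulting curve has the required triple-valley shape: minima at
l = 0, 1.000 and 2.099 l̄, barrier tops at 0.293 and 1.574 l̄, barrier height
≈ 0.1 Ē ≈ 1 k_BT.  Because the near wall's singularity (l_min = −0.05)
lies below the physical domain, the near valley's minimum sits exactly at
the grid origin; one consequence is that the initial critical-point
segmentation has six distinct critical points and five initial segments
rather than the nominal seven/six (the near-valley minimum and the lower
grid boundary coincide).

The spring constant of external control points, k_ex = 20 Ē/l̄², is not part
of the published parameter table; it is chosen so control-point springs
dominate bending at l̄-scale displacements, and is configurable.

**Forces.**  Every force is the exact analytic negative gradient of its
energy: the pairwise internal force, the full gradient of the discrete
Helfrich energy (including the dependence of the cotangent weights and the
mixed areas on the positions; the energy of a vertex depends only on its
star, so the 1-ring force stencil is complete, not a truncation), the
signed-volume and area gradients, the mixed-area gradient behind the local
tension, and Hookean control-point springs.  Each is verified against a
central finite difference of its energy in the test suite (≤ 1e-3 relative
for the bending force, tighter elsewhere).  The volume/area penalty
gradient at a vertex is replaced by the mean of the raw gradients over the
vertex and its 1-ring before it enters the total force, which smooths the
penalty forces.

## Adaptive dynamics

V_in is sampled on the grid l = 0, dl, …, M·dl with M = l_max/dl − 1
(21999 at defaults; the omitted last point avoids the wall singularity).
The grid is segmented starting from the critical points and recursively
bisected at segment midpoints until each segment's linear fit has R² > 0.5
and residual σ < 0.001·V0.  σ is the standard deviation of the residuals
about the fit (a raw-value σ would bisect nearly everything to single grid
points and contradict the possibility of long linear segments); raw-σ mode
is available behind a flag.  Constant-to-machine-precision segments pass
the R² test by convention, and single-grid-point segments that still fail
are accepted with a logged warning.  Segment membership is half-open: a
boundary length belongs to the lower-index segment.

Each step, the candidate end length of every edge is the midpoint of its
neighboring segment on either side; inverting the first-order length update
gives a forward and a backward candidate Δt sharing one denominator, of
which exactly one is positive.  The global step is the minimum over edges,
clamped to (Δt_min, Δt_max] = (1e-9, 1e-3] s̄ by default (both
configurable; clamping is recorded).  Two additions stabilize the scheme:

- **Displacement cap** (default 0.05 l̄ per vertex per step): forces along
  vertex normals change edge lengths only at second order, so the segment
  rule alone would let stiff bending or penalty forces overshoot in the
  normal direction.
- **Self-consistent noise amplitude**: the time-averaged stochastic force
  ξ = ε √(2 μ k_BT Δt)/(μ Δt) depends on Δt while Δt depends on the total
  force including ξ; the pair is iterated to a fixed point (Δt decreases
  monotonically and the noise displacement ∝ √Δt decreases with it, so a
  few iterations suffice).

The one-segment guarantee is exact at the order of the derivation: the
first-order predicted length change never carries an edge past the midpoint
of a neighboring segment (asserted for every edge and step in the tests);
the residual beyond first order is exactly |Δr_j − Δr_i|², which can cross
additional ultra-fine segments near the potential's critical points.

## Remeshing

Edges beyond l_+ = 1.3 (splits) or below l_− = 0.7 (merges) are processed
one at a time, most deviant first, with global dynamics paused.  The local
relaxation moves the edge's endpoints and their 1-rings (2-ring frozen)
under the patch-restricted internal force plus biased α-stable noise
(α = 1.5, scale 0.01 l̄, bias 0.02 l̄ per sweep; per-sweep moves clipped to
0.1 l̄ so the diverging walls cannot catapult a vertex).  The endpoint
1-rings co-move with half the drive weight — otherwise the target edge's
own adjacent edges cancel the drive; out-of-range bystander edges receive a
restoring bias (0.3 weight inside the barrier band, full weight once an
edge has crossed into the wrong valley).

The completion rule uses the barrier top as a separatrix: the weak bias
cannot carry a marginally triggered edge over the barrier against the
internal force, so reaching the finish threshold (l_++ = 1.7 extension,
l_−− = 0.1 compression) reports whether the global deformation has pushed
the edge near the barrier top.  Failure is declared when the edge falls
back into its valley basin (0.1 l̄ of hysteresis below/above the trigger —
hovering at the trigger is not a verdict) while the rest of the patch is in
range, or when progress stalls.  Failed events restore positions,
connectivity and densities bit-exactly, and a per-edge cooldown (40 steps)
spaces retries; sustained deformation therefore ratchets an edge deeper
between attempts, while thermal excursions relax back.  This combination is
what makes the method selective: in the vesicle-fusion comparison the
free-energy remesher fires two orders of magnitude fewer events than the
geometry baseline, clustered where the shape actually changes.

A successful split inserts the midpoint vertex and reconnects four
quadrilaterals (2⁴ = 16 diagonal assignments); a merge collapses the edge
to its midpoint and reconnects two (2² = 4).  Options that leave any
valence outside [5, 8], duplicate an existing edge, or (for merges) involve
endpoints sharing more than the two opposite vertices are discarded; among
the survivors the assignment minimizing the valence variance wins, ties
broken by the lexicographic option index.  Densities are reassigned
exactly: a split shares the two endpoint densities equally among the three
involved vertices; a merge sums them.  A best-effort settle relaxation then
drives the new edges into (l_−, l_+); edges it cannot settle stay flagged
and trigger follow-up events — the cascade by which a collectively
deformed region (for example a fusion neck) is resolved one event at a
time.  Control points whose target vertex is removed by a merge are
remapped to the surviving vertex.

The geometry baseline ("Geo") uses the same machinery with V_in = 0 in the
dynamics and no completion test: pure length triggers acting immediately,
with the same retriangulation and the same settle relaxation.

## Lipid density and tension

After every successful remeshing event the density master equation runs for
n_d = 50 synchronous iterations: each vertex sends k_d·ρ(i)/v(i) along each
of its v(i) edges and receives the matching share from its neighbors.
Fluxes are suppressed pairwise on blocked edges, so the total density is
conserved exactly under any barrier mask; k_d < 1 keeps densities positive.
The stationary state of this equation weights vertices by valence (uniform
density is stationary only on regular meshes) — the equilibration-rate test
checks the decay toward that state against the spectral gap of the exact
update matrix on a small mesh.

A diffusion barrier blocks all edges in a geometric band except a seeded
random 6% left permeable; the fully blocked band must disconnect the mesh
graph (checked via connected components).  Because remeshing changes edge
identity, the scenario loop rebuilds the mask from the band predicate with
a dedicated RNG stream before each post-event diffusion; the permeable
fraction is maintained throughout rather than a fixed edge set.  The
membrane reservoir scales the reference area field s0 by 1.33
(idempotent).  The local tension's per-vertex area is s(i) := A_v(i), its
reference s0 the mixed areas of the pull-start morphology, remapped on
remeshing (split children interpolate their parents' s0; merges sum), and
the reference density ρ0 follows the same bookkeeping as the live density.

## Scenarios and measurements

- **Red blood cell**: a sphere (mean edge l0) with S0 at its initial area
  and V0 ramped to 60% of the initial volume (a sudden target drop crumples
  the membrane and triggers a merge cascade that removes area-carrying
  vertices faster than tension-driven splits can restore them).  The
  equilibrium-shape check runs the noise-free limit (k_BT = 0,
  Δt_max = 1e-2, displacement cap 0.15 l̄) with deflation annealing: the
  volume target is cycled (re-inflated and re-ramped every 10⁴ steps,
  3×10³-step ramps), which pumps the shape over the oblate/stomatocyte
  hysteresis into the symmetric discocyte that a single monotone deflation
  fails to reach at this resolution.  At 642 vertices the result is a clear
  discocyte by thickness profile (axial thickness ≈ 1 l̄ against ≈ 2.2 l̄ on
  the torus ring) whose shallow caps keep a positive pointwise mean
  curvature.  With
  thermal noise at k_BT = Ē/10 the coarse meshes lose area through the
  merge cascade and stall before the dimple — a genuine resolution
  limitation at these scaled-down sizes.
- **Vesicle fusion / method comparison**: two subdivision-n icospheres
  bridged by a single triangulated neck (facing vertices removed, boundary
  loops stitched; the default separation keeps the bridge edges inside the
  working band).  V0 and S0 are the two-sphere totals.  The comparison runs
  matched seeds in FE and Geo modes and reports the success-count ratio and
  the ratio of event-coordinate spreads, where the spread is the rms of the
  per-axis standard deviations of the centroid-centered event coordinates
  (translation invariant; an |r|-based spread would compress the
  neck-versus-global contrast for this axially elongated geometry).
- **Protrusions**: filopodia (three tip control points), a lamellipodial
  rim (control points advanced at half run), an invagination (a point one
  third into the cell), each with equatorial holder points.
- **Tether pulling**: two control points at ±x pull tethers from a sphere
  held by four equatorial anchors; after initialization the energy switches
  to the density-weighted local tension with the pull-start morphology as
  reference, and the left point is advanced in increments.  Tether radius
  is the mean axial-band distance from the pull axis at the tether's
  midpoint station, in the lab frame fixed by the holders (a
  centroid-relative station would slide with the pulled center of mass),
  normalized to the pull-start value; the per-frame series is fitted with a
  fourth-order polynomial and the fit's final value is the coupling
  readout, scanned over k_d and membrane condition (naive / barrier /
  barrier + reservoir) over seed ensembles.

## Problem sizes

The full-scale study settings (5×10⁴ iterations for shape relaxations,
2×10⁴ for protrusions and the comparison, 8-seed k_d scans) are retained as
the drivers' documented defaults.  The test suite and the acceptance script
run reduced versions chosen as the smallest sizes at which each qualitative
claim is stable: subdivision-2 meshes and a 400-step window for the
FE/Geo comparison (2 seed pairs), 22000 deterministic steps at subdivision
3 for the discocyte, 700 + 600 steps and 2 seeds per condition at
k_d = 0.25 for the tether ordering, and a 60-cycle randomized split/merge
ensemble for exact density conservation.

## Known limitations

- Genus-0 closed surfaces only; no Gaussian-curvature or area-difference
  elasticity terms; no rupture/topological repair (a tether pinching to a
  single-vertex connection invalidates the run).
- The one-segment rule is first-order; second-order normal motion can cross
  ultra-fine segments near the potential's critical points.
- The Levy-relaxation parameters (bias, scale, stall window, cooldown) are
  not part of the published parameter set; the defaults here were chosen so
  that deformation-driven crossings complete and marginal thermal triggers
  do not, and they set the method's selectivity.
- At the scaled-down mesh resolutions used in the tests, thermally agitated
  runs of strongly deflated shapes under-resolve the area-preserving folds
  and lose area through merges; the noise-free limit is used for
  equilibrium-shape claims.
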