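# memremesh

Free-energy-controlled remeshing of flexible closed membranes.

Cell membranes undergo large shape changes — red blood cells settling into
their biconcave rest shape, vesicles fusing, filopodia and membrane tethers
being pulled out by the cytoskeleton or an optical tweezer.  Simulating
these processes on a triangulated surface runs into a dilemma: if the mesh
connectivity is fixed, large deformations degrade triangle quality until
curvature (and hence bending energy) can no longer be computed reliably;
if the mesh is repaired by geometric rules alone, the repairs are divorced
from the physics.  `memremesh` implements a method that makes remeshing
itself part of the free-energy minimization: every pair of connected
vertices interacts through a triple-valley potential of the edge length,
and the mesh is rewritten exactly when an edge crosses one of the
potential's barriers.

## Model

The membrane is a closed, oriented triangle mesh.  Its total free energy is

    E = E_in + H + E_v + E_s (+ E_ex)

- **Internal potential** `E_in = Σ_edges V_in(l)`: `V_in` has valleys near
  `l = 0`, `l0` and `2 l0`, two barriers between them, and walls that
  diverge at `l_min` and `l_max`.  An edge driven past the far barrier has
  doubled its rest length and is split (a midpoint vertex is inserted); an
  edge driven past the near barrier is merged (its endpoints collapse).
- **Helfrich bending** `H = κ/2 Σ_i A_v(i) (2|C(i)| − C0)²` with the
  cotangent-weight mean-curvature operator and mixed Voronoi areas
  (`C0 = 0` throughout).
- **Volume and area penalties** `E_v = k_v (V − V0)²/V0`,
  `E_s = k_s (S − S0)²/S0` (osmotic pressure and global tension); for the
  tether experiments the area term is replaced by a density-weighted local
  tension `E_s' = k_s' Σ_i (s_i/ρ_i − s0_i/ρ0_i)²/(s0_i/ρ0_i)` coupled to a
  per-vertex lipid density ρ that diffuses between neighbors and is
  redistributed by every split and merge.
- **External control points**: fixed anchors coupled to target vertices and
  their 1-rings by Hookean springs (`k_ex`), used to pull tethers and shape
  protrusions.

Vertices move by an overdamped Langevin equation whose time step adapts so
that no edge sweeps more than one segment of a piecewise-linear
segmentation of `V_in` per step.  Barrier crossings pause the global
dynamics; a local relaxation (internal forces plus biased heavy-tailed
noise, with the 2-ring frozen) decides whether the crossing completes, a
valence-constrained retriangulation (valences kept in [5, 8]) rewires the
neighborhood, and the lipid density is reassigned exactly.

Units are natural: energy 10 k_BT, length 1000 nm, time 1 s.

## Worked example

Stretch one edge of a taut spherical membrane near the far barrier and let
the method decide:

```python
import numpy as np
from memremesh.io_cli import SimulationConfig, icosphere_with_edge
from memremesh import remeshing as rm

cfg = SimulationConfig()               # physical defaults in natural units
mesh = icosphere_with_edge(2, 1.0)     # 162 vertices, mean edge = l0
mesh.positions *= 1.1                  # taut membrane
e = mesh.edges[40]
d = mesh.positions[e[1]] - mesh.positions[e[0]]
mesh.positions[e[1]] += (1.6 / np.linalg.norm(d) - 1.0) * d  # deep stretch

edge, kind = rm.detect_bce(mesh, cfg.potential)[0]
event = rm.split_edge(mesh, edge, cfg, np.random.default_rng(0))
print(kind, event.outcome, mesh.n_vertices, mesh.density[list(event.edge)])
```

prints

```
split success 163 [0.66666667 0.66666667]
```

one split completed: the mesh gained a vertex (162 → 163), and the two
unit-density endpoints now share their lipids three ways (ρ = 2/3 each,
with the new midpoint vertex carrying the remaining third).  The same edge
nudged only just past the trigger on a relaxed sphere reports
`bce_failed` and the mesh is restored bit-exactly — thermally triggered
crossings do not complete, deformation-driven ones do.

Scenario drivers live in `memremesh.scenarios` (`run_rbc`, `run_fusion`,
`run_protrusion`, `run_tether_experiment`, `tether_kd_scan`) and behind the
`memremesh` command line:

```
memremesh run fusion --mode Geo --steps 2000 --subdivisions 2 --out out/geo
memremesh compare --fe out/fe --geo out/geo
memremesh scan-kd --condition barrier --seeds 8
```

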