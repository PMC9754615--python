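"""Lipid-density diffusion on the mesh graph, barriers and the reservoir.

Remeshing leaves step changes in the normalized lipid density; a discrete
master equation relaxes them by exchanging density between 1-ring neighbors.
A diffusion barrier (a band of edges that forbids exchange except across a
small permeable fraction) and a membrane reservoir (reference area scaled
up) are the two mechanisms that decelerate tension propagation between
membrane tethers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .trimesh_core import TriMesh


@dataclasses.dataclass
class BarrierMask:
    """Blocked mesh edges (vertex-id pairs) and the permeable exceptions."""

    blocked: set          # frozenset of (u, v) sorted tuples with no flux
    band: set             # all edges in the barrier band
    permeable: set        # band edges left open
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"blocked": sorted(self.blocked), "band": sorted(self.band),
                "permeable": sorted(self.permeable), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "BarrierMask":
        return cls(blocked={tuple(e) for e in d["blocked"]},
                   band={tuple(e) for e in d["band"]},
                   permeable={tuple(e) for e in d["permeable"]},
                   seed=d.get("seed"))


def diffuse_density(mesh: TriMesh, k_d: float, n_d: int,
                    mask: BarrierMask | None = None) -> np.ndarray:
    """Run the density master equation for n_d synchronous iterations.

    Per iteration every vertex sends k_d * rho(i)/v(i) along each of its
    v(i) edges and receives the matching share from each neighbor; blocked
    edges carry no flux in either direction (suppressed pairwise, so the
    total density is conserved exactly).  Updates mesh.density in place and
    returns it.
    """
    if not (0.0 < k_d < 1.0):
        raise ValueError("k_d must lie in (0, 1): the update overshoots otherwise")
    edges = mesh.edges
    if mask is not None and mask.blocked:
        keep = np.array([(int(a), int(b)) not in mask.blocked
                         for a, b in edges])
        open_edges = edges[keep]
    else:
        open_edges = edges
    v = mesh.valences.astype(float)  # full valence, blocked edges included
    i, j = open_edges[:, 0], open_edges[:, 1]
    rho = mesh.density
    for _ in range(n_d):
        flux = k_d * (rho[j] / v[j] - rho[i] / v[i])  # j -> i along each edge
        delta = np.zeros_like(rho)
        np.add.at(delta, i, flux)
        np.add.at(delta, j, -flux)
        rho = rho + delta
    mesh.density = rho
    return rho


def make_barrier(mesh: TriMesh, band_region, permeable_fraction: float,
                 rng: np.random.Generator) -> BarrierMask:
    """Block a band of edges, leaving a seeded random fraction permeable.

    ``band_region`` is a predicate evaluated on edge midpoints.  The fully
    blocked band must separate the mesh graph into at least two components
    (checked explicitly); a permeable_fraction of 1 blocks nothing.
    """
    edges = mesh.edges
    mids = 0.5 * (mesh.positions[edges[:, 0]] + mesh.positions[edges[:, 1]])
    in_band = np.array([bool(band_region(m)) for m in mids])
    band = {(int(a), int(b)) for a, b in edges[in_band]}
    if not band:
        raise ValueError("band predicate selects no edges")
    # the closed band must separate the two regions
    keep = ~in_band
    n = mesh.n_vertices
    adj = coo_matrix((np.ones(keep.sum()),
                      (edges[keep, 0], edges[keep, 1])), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp < 2:
        raise ValueError("barrier band does not separate the mesh")
    band_list = sorted(band)
    n_open = int(round(permeable_fraction * len(band_list)))
    perm_idx = rng.choice(len(band_list), size=n_open, replace=False)
    permeable = {band_list[k] for k in perm_idx}
    seed = None
    return BarrierMask(blocked=band - permeable, band=band,
                       permeable=permeable, seed=seed)


RESERVOIR_SCALE = 1.33  # 33% excess reference membrane area


def apply_reservoir(cfg) -> None:
    """Scale the local-tension reference area s0 up by 33% (idempotent)."""
    if cfg.s0_field is None:
        raise ValueError("config has no reference s0 field")
    if getattr(cfg, "_reservoir_applied", False):
        return
    cfg.s0_field = RESERVOIR_SCALE * np.asarray(cfg.s0_field)
    cfg._reservoir_applied = True
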