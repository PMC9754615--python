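"""Closed, oriented triangle-mesh data structure and discrete-geometry operators.

The mesh is the membrane representation: vertices carry positions (natural
length units) and a normalized lipid density; faces are ordered vertex triples
following the right-hand rule with outward normals.  All per-vertex energy
terms downstream are built on the operators here: the mixed (Voronoi) vertex
area, the cotangent-weight mean-curvature operator, and the signed enclosed
volume / total surface area.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh as _trimesh_lib

COT_CLAMP = 1e8  # survive near-degenerate triangles occurring mid-relaxation


class MeshError(ValueError):
    """Raised when a mesh violates a structural precondition."""


@dataclasses.dataclass
class ValidationReport:
    ok: bool
    message: str

    def __bool__(self) -> bool:
        return self.ok


class TriMesh:
    """Oriented closed triangle mesh with per-vertex lipid density.

    Parameters
    ----------
    positions : (V, 3) float array
        Vertex coordinates.
    faces : (F, 3) int array
        Ordered vertex-index triples (right-hand rule, outward normal).
    density : (V,) float array, optional
        Normalized lipid density; defaults to 1 everywhere.
    """

    def __init__(self, positions, faces, density=None):
        self.positions = np.ascontiguousarray(positions, dtype=float)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise MeshError("positions must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (F, 3)")
        if density is None:
            density = np.ones(len(self.positions))
        self.density = np.asarray(density, dtype=float).copy()
        if self.density.shape != (len(self.positions),):
            raise MeshError("density must be (V,)")
        self._cache: dict = {}

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def invalidate(self) -> None:
        """Drop derived caches after any mutation of positions or faces.

        Position-only updates need not invalidate (caches below depend only
        on connectivity), but remeshing must call this.
        """
        self._cache.clear()

    def copy(self) -> "TriMesh":
        return TriMesh(self.positions.copy(), self.faces.copy(), self.density.copy())

    # -- connectivity caches ----------------------------------------------

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) undirected edges, each row sorted, rows lexsorted."""
        if "edges" not in self._cache:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
            e.sort(axis=1)
            e = np.unique(e, axis=0)
            self._cache["edges"] = e
        return self._cache["edges"]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_index(self) -> dict:
        """Map (min, max) vertex pair -> edge row index."""
        if "edge_index" not in self._cache:
            self._cache["edge_index"] = {
                (int(a), int(b)): k for k, (a, b) in enumerate(self.edges)
            }
        return self._cache["edge_index"]

    @property
    def edge_faces(self) -> np.ndarray:
        """(E, 2) face indices adjacent to each edge (-1 marks a boundary)."""
        if "edge_faces" not in self._cache:
            ef = np.full((self.n_edges, 2), -1, dtype=np.int64)
            idx = self.edge_index
            for f, (a, b, c) in enumerate(self.faces):
                for u, v in ((a, b), (b, c), (c, a)):
                    key = (int(min(u, v)), int(max(u, v)))
                    k = idx[key]
                    if ef[k, 0] < 0:
                        ef[k, 0] = f
                    elif ef[k, 1] < 0:
                        ef[k, 1] = f
                    else:
                        ef[k, 0] = -2  # over-shared, caught by validate
            self._cache["edge_faces"] = ef
        return self._cache["edge_faces"]

    @property
    def vertex_faces(self) -> list:
        if "vertex_faces" not in self._cache:
            vf = [[] for _ in range(self.n_vertices)]
            for f, tri in enumerate(self.faces):
                for v in tri:
                    vf[v].append(f)
            self._cache["vertex_faces"] = vf
        return self._cache["vertex_faces"]

    def one_ring(self, i: int) -> np.ndarray:
        """Cyclically ordered 1-ring neighbors of vertex ``i``.

        The cycle follows the face orientation (counter-clockwise seen from
        outside) and starts at the smallest-index neighbor so the order is
        deterministic, which the remeshing retriangulation relies on.
        """
        rings = self._one_rings()
        ring = rings[i]
        if ring is None:
            raise MeshError(f"non-manifold neighborhood at vertex {i}")
        return ring

    def _one_rings(self) -> list:
        if "one_rings" not in self._cache:
            succ: list = [dict() for _ in range(self.n_vertices)]
            for a, b, c in self.faces:
                # around vertex a, neighbor b is followed by c, etc.
                succ[a][int(b)] = int(c)
                succ[b][int(c)] = int(a)
                succ[c][int(a)] = int(b)
            rings = []
            for i in range(self.n_vertices):
                s = succ[i]
                if not s:
                    rings.append(None)
                    continue
                start = min(s)
                cyc = [start]
                cur = s[start]
                ok = True
                while cur != start:
                    if cur in cyc or cur not in s:
                        ok = False
                        break
                    cyc.append(cur)
                    cur = s[cur]
                if not ok or len(cyc) != len(s):
                    rings.append(None)
                else:
                    rings.append(np.array(cyc, dtype=np.int64))
            self._cache["one_rings"] = rings
        return self._cache["one_rings"]

    @property
    def valences(self) -> np.ndarray:
        if "valences" not in self._cache:
            v = np.zeros(self.n_vertices, dtype=np.int64)
            np.add.at(v, self.edges[:, 0], 1)
            np.add.at(v, self.edges[:, 1], 1)
            self._cache["valences"] = v
        return self._cache["valences"]

    def edge_lengths(self) -> np.ndarray:
        d = self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces


# -- per-triangle geometry kernel ------------------------------------------


def triangle_geometry(mesh: TriMesh):
    """Per-face areas, cotangents and mixed-area contributions.

    Returns a dict with, for faces ``(i0, i1, i2)``:

    - ``area``: (F,) triangle areas,
    - ``cot``: (F, 3) cotangent of the angle at each corner,
    - ``mixed``: (F, 3) the share of the triangle assigned to each corner by
      the mixed-area rule (exact Voronoi split for non-obtuse triangles,
      half/quarter clamping for obtuse ones, so the shares tile the surface).
    """
    p = mesh.positions[mesh.faces]  # (F, 3, 3)
    # edge vectors opposite each corner: e[k] = p[(k+2)] - p[(k+1)]
    e = p[:, [2, 0, 1], :] - p[:, [1, 2, 0], :]  # (F, 3, 3)
    l2 = np.einsum("fkx,fkx->fk", e, e)  # squared edge lengths opposite corners
    e1, e2 = e[:, 1, :], e[:, 2, :]
    n = np.empty_like(e1)  # = (p0-p2) x (p1-p0) ~ 2A * normal
    n[:, 0] = e1[:, 1] * e2[:, 2] - e1[:, 2] * e2[:, 1]
    n[:, 1] = e1[:, 2] * e2[:, 0] - e1[:, 0] * e2[:, 2]
    n[:, 2] = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    double_area = np.linalg.norm(n, axis=1)
    area = 0.5 * double_area
    # cot at corner k: dot of the two edge vectors leaving corner k over 2A.
    # edges leaving corner k are -e[(k+1)] and e[(k+2)] ... derive via l2:
    # cot_k = (l2_{k+1} + l2_{k+2} - l2_k) / (4 A)
    with np.errstate(divide="ignore", invalid="ignore"):
        cot = (l2[:, [1, 2, 0]] + l2[:, [2, 0, 1]] - l2) / (2.0 * double_area[:, None])
    cot = np.clip(np.nan_to_num(cot, nan=0.0, posinf=COT_CLAMP, neginf=-COT_CLAMP),
                  -COT_CLAMP, COT_CLAMP)
    # mixed-area shares
    voronoi = (l2[:, [2, 0, 1]] * cot[:, [2, 0, 1]] + l2[:, [1, 2, 0]] * cot[:, [1, 2, 0]]) / 8.0
    obtuse = cot < 0.0  # corner k obtuse
    any_obtuse = obtuse.any(axis=1)
    mixed = voronoi.copy()
    if np.any(any_obtuse):
        rows = np.where(any_obtuse)[0]
        share = np.full((len(rows), 3), 0.25)
        share[obtuse[rows]] = 0.5
        mixed[rows] = share * area[rows, None]
    return {"area": area, "cot": cot, "mixed": mixed, "normal2A": n, "l2": l2}


def mixed_voronoi_area(mesh: TriMesh, i: int | None = None):
    """Mixed Voronoi area A_v per vertex (or for a single vertex ``i``).

    The shares tile the surface exactly: sum_i A_v(i) == surface_area(mesh).
    """
    geo = triangle_geometry(mesh)
    if np.any(geo["area"] <= 0.0):
        raise MeshError("degenerate (zero-area) triangle")
    av = np.zeros(mesh.n_vertices)
    av += np.bincount(mesh.faces.ravel(), geo["mixed"].ravel(), minlength=mesh.n_vertices)
    return av if i is None else float(av[i])


def mean_curvature_operator(mesh: TriMesh, i: int | None = None):
    """Cotangent-weight mean-curvature operator K(i).

    K(i) = 1/(2 A_v(i)) * sum_j (cot theta_ij + cot phi_ij) (r_i - r_j);
    the unsigned mean curvature is |C(i)| = |K(i)| / 2.  For a convex mesh
    with outward orientation K points inward.
    """
    geo = triangle_geometry(mesh)
    if np.any(geo["area"] <= 0.0):
        raise MeshError("degenerate triangle: angle of 0 or pi")
    T = cot_laplacian_vector(mesh, geo)
    av = np.zeros(mesh.n_vertices)
    av += np.bincount(mesh.faces.ravel(), geo["mixed"].ravel(), minlength=mesh.n_vertices)
    K = T / (2.0 * av[:, None])
    return K if i is None else K[i]


def cot_laplacian_vector(mesh: TriMesh, geo=None) -> np.ndarray:
    """T(i) = sum_j (cot theta_ij + cot phi_ij) (r_i - r_j), accumulated per face."""
    if geo is None:
        geo = triangle_geometry(mesh)
    p = mesh.positions[mesh.faces]
    T = np.zeros((mesh.n_vertices, 3))
    # in face (v0, v1, v2): cot at corner k weights edge (k+1, k+2)
    for k in range(3):
        a, b = (k + 1) % 3, (k + 2) % 3
        w = geo["cot"][:, k][:, None]
        d = w * (p[:, a, :] - p[:, b, :])
        for c in range(3):
            T[:, c] += np.bincount(mesh.faces[:, a], d[:, c], minlength=mesh.n_vertices)
            T[:, c] -= np.bincount(mesh.faces[:, b], d[:, c], minlength=mesh.n_vertices)
    return T


def enclosed_volume(mesh: TriMesh) -> float:
    """Signed volume sum_faces det(r0, r1, r2) / 6; positive when outward."""
    _require_closed(mesh)
    p = mesh.positions[mesh.faces]
    return float(np.einsum("fx,fx->f", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0)


def surface_area(mesh: TriMesh) -> float:
    _require_closed(mesh)
    return float(triangle_geometry(mesh)["area"].sum())


def _require_closed(mesh: TriMesh) -> None:
    if np.any(mesh.edge_faces < 0):
        raise MeshError("mesh is not closed (boundary or non-manifold edge)")


# -- constructors ----------------------------------------------------------


def build_icosphere(subdivisions: int, radius: float = 1.0) -> TriMesh:
    """Icosphere with 10 * 4**n + 2 vertices, uniform density 1, outward faces."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    m = _trimesh_lib.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh = TriMesh(np.asarray(m.vertices), np.asarray(m.faces))
    if enclosed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
        mesh.invalidate()
    return mesh


def build_fused_spheres(subdivisions: int, radius: float = 1.0,
                        separation: float | None = None) -> TriMesh:
    """Two icospheres bridged by a single triangulated neck (closed, genus 0).

    The facing vertex of each sphere is removed and the two boundary loops are
    stitched with a triangle band.  ``separation`` is the center-to-center
    distance; the default leaves a neck of roughly one edge length.
    """
    left = build_icosphere(subdivisions, radius)
    if separation is None:
        # place the spheres so the bridging band edges stay moderate: the
        # facing vertices are removed, so the gap is measured between the
        # two boundary loops, not between the poles
        x_loop = float(left.positions[left.one_ring(int(np.argmax(left.positions[:, 0])))][:, 0].mean())
        separation = 2.0 * x_loop + 0.7 * float(left.edge_lengths().mean())
    if separation < 2.0 * radius * 0.8:
        raise MeshError("separation would interpenetrate the spheres")

    # mirror the left sphere to get the right one: congruent facing holes
    right_pos = left.positions * np.array([-1.0, 1.0, 1.0])
    right_faces = left.faces[:, ::-1]  # restore orientation after mirroring

    iL = int(np.argmax(left.positions[:, 0]))
    loopL = left.one_ring(iL)

    keepL = np.ones(left.n_vertices, bool)
    keepL[iL] = False
    facesL = left.faces[~np.any(left.faces == iL, axis=1)]
    facesR = right_faces[~np.any(right_faces == iL, axis=1)]

    offL = left.positions[keepL] + np.array([-separation / 2.0, 0.0, 0.0])
    offR = right_pos[keepL] + np.array([separation / 2.0, 0.0, 0.0])

    remap = np.full(left.n_vertices, -1, dtype=np.int64)
    remap[keepL] = np.arange(keepL.sum())
    nL = keepL.sum()
    facesL = remap[facesL]
    facesR = remap[facesR] + nL

    # the left hole boundary keeps its one-ring cyclic order; each left-loop
    # vertex faces its own mirror image (same index, offset by nL), and the
    # mirrored hole is traversed in the opposite sense, so quads
    # (La, Lb, Mb, Ma) with b = a+1 wind consistently with both holes.
    loop_left = remap[loopL]
    loop_mirror = remap[loopL] + nL

    m = len(loop_left)
    band = []
    for a in range(m):
        b = (a + 1) % m
        la, lb = loop_left[a], loop_left[b]
        ma, mb = loop_mirror[a], loop_mirror[b]
        band.append([la, lb, mb])
        band.append([la, mb, ma])
    faces = np.vstack([facesL, facesR, np.array(band, dtype=np.int64)])
    mesh = TriMesh(np.vstack([offL, offR]), faces)
    rep = validate_mesh(mesh)
    if not rep:
        raise MeshError(f"fused-sphere bridging failed: {rep.message}")
    if enclosed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
        mesh.invalidate()
    return mesh


# -- validation ------------------------------------------------------------


def validate_mesh(mesh: TriMesh, check_valence_band: bool = False) -> ValidationReport:
    """Check the closed-2-manifold invariants; report the first violation.

    ``check_valence_band`` additionally enforces valences in [5, 8] (the
    remeshing contract; initial icosahedra legitimately violate it only in
    that every vertex has valence 5-6, which passes).
    """
    f = mesh.faces
    if len(f) == 0:
        return ValidationReport(False, "empty mesh")
    if f.min() < 0 or f.max() >= mesh.n_vertices:
        return ValidationReport(False, "face index out of range")
    if np.any(f[:, 0] == f[:, 1]) or np.any(f[:, 1] == f[:, 2]) or np.any(f[:, 0] == f[:, 2]):
        return ValidationReport(False, "degenerate face (repeated vertex)")
    directed = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    d_view = directed[np.lexsort(directed.T[::-1])]
    dup = np.all(d_view[1:] == d_view[:-1], axis=1)
    if np.any(dup):
        return ValidationReport(False, "orientation: duplicated directed edge")
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    if np.any(counts != 2):
        bad = uniq[counts != 2][0]
        kind = "boundary" if counts[counts != 2][0] == 1 else "over-shared"
        return ValidationReport(False, f"{kind} edge {tuple(bad)}")
    # every directed edge must appear exactly once in each direction
    # (counts == 2 with no duplicated directed edge already guarantees this)
    chi = mesh.n_vertices - len(uniq) + len(f)
    if chi != 2:
        return ValidationReport(False, f"Euler characteristic {chi} != 2")
    val = mesh.valences
    if val.min() < 3:
        return ValidationReport(False, f"valence {val.min()} < 3")
    if check_valence_band and (val.min() < 5 or val.max() > 8):
        return ValidationReport(False, "valence outside [5, 8]")
    if np.any(mesh.density <= 0):
        return ValidationReport(False, "non-positive lipid density")
    if any(r is None for r in mesh._one_rings()):
        return ValidationReport(False, "non-manifold vertex star")
    return ValidationReport(True, "ok")
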