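"""Free-energy terms of the membrane and their (analytic) forces.

Terms
-----
- internal potential ``V_in``: a triple-valley function of edge length with
  minima near 0, ``l0`` and ``2*l0``, two barriers in between and diverging
  walls at ``l_min``/``l_max``.  Barrier bumps are opposed logistic sigmoids,
  the walls are coth terms, singular at the bounds.
- Helfrich bending energy on the triangulated surface, via the cotangent
  mean-curvature operator and mixed Voronoi areas.
- quadratic penalties on total enclosed volume and surface area (osmotic
  pressure / global tension).
- density-weighted local tension, coupling the per-vertex area to the
  normalized lipid density.
- Hookean springs to fixed external control points (rigid cytoskeletal or
  optical-tweezer attachments).

All energies are in natural energy units (1 unit = 10 k_B T), lengths in
units of 1000 nm, times in seconds.  Every force here is the exact analytic
negative gradient of its energy; tests verify each against central finite
differences.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .trimesh_core import (
    MeshError,
    TriMesh,
    cot_laplacian_vector,
    enclosed_volume,
    triangle_geometry,
)

KBT = 0.1  # k_B T in natural energy units (1 unit = 10 k_B T)

def _scat3(out, idx, vals):
    """out[idx] += vals for (N,3) accumulators (bincount beats np.add.at)."""
    n = len(out)
    out[:, 0] += np.bincount(idx, vals[:, 0], minlength=n)
    out[:, 1] += np.bincount(idx, vals[:, 1], minlength=n)
    out[:, 2] += np.bincount(idx, vals[:, 2], minlength=n)


def _scat1(out, idx, vals):
    out += np.bincount(np.ravel(idx), np.ravel(vals), minlength=len(out))




# =========================================================================
# Internal potential V_in
# =========================================================================


@dataclasses.dataclass
class PotentialParams:
    """Parameters of the triple-valley edge potential (natural units)."""

    V0: float = 0.2       # overall scale
    b: float = 0.5        # relative barrier height
    r11: float = 0.05     # near barrier, rising flank
    r12: float = 0.75     # near barrier, falling flank
    r21: float = 1.25     # far barrier, rising flank
    r22: float = 1.75     # far barrier, falling flank
    k11: float = 50.0
    k12: float = 25.0
    k21: float = 25.0
    k22: float = 50.0
    kw: float = 100.0     # wall steepness
    lmin: float = -0.05   # near wall singularity (below the physical range)
    lmax: float = 2.2     # far wall singularity
    l0: float = 1.0       # default edge length
    dl: float = 1e-4      # sampling grid spacing
    l_mm: float = 0.1     # compressive BCE finish
    l_m: float = 0.7      # compressive BCE trigger
    l_p: float = 1.3      # extensive BCE trigger
    l_pp: float = 1.7     # extensive BCE finish

    def __post_init__(self):
        if not (self.lmin < 0 <= self.r11 < self.r12 < self.r21
                < self.r22 < self.lmax):
            raise ValueError("potential landmarks out of order")
        if not (self.l_mm < self.l_m < self.l0 < self.l_p < self.l_pp):
            raise ValueError("BCE thresholds out of order")
        self._vprime = None

    @property
    def grid_size(self) -> int:
        """M such that the grid is l = 0, dl, ..., M*dl (M = lmax/dl - 1)."""
        return int(round(self.lmax / self.dl)) - 1

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_size + 1) * self.dl

    @property
    def vprime(self) -> float:
        """Offset making min V_in = 0 hold exactly on the sampling grid."""
        if self._vprime is None:
            self._vprime = -float(np.min(_v_in_raw(self.grid(), self)))
        return self._vprime


def _sigmoid(x):
    # numerically safe logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _v_in_raw(l, p: PotentialParams):
    """V_in without the constant offset; vectorized over l."""
    l = np.asarray(l, dtype=float)
    near = _sigmoid(p.k11 * (l - p.r11)) + _sigmoid(p.k12 * (p.r12 - l))
    far = _sigmoid(p.k21 * (l - p.r21)) + _sigmoid(p.k22 * (p.r22 - l))
    walls = 1.0 / np.tanh(p.kw * (l - p.lmin)) + 1.0 / np.tanh(p.kw * (p.lmax - l))
    return p.V0 * (p.b * (near + far) + walls)


def _v_in_raw_deriv(l, p: PotentialParams):
    l = np.asarray(l, dtype=float)

    def dsig(x, k):
        s = _sigmoid(x)
        return k * s * (1.0 - s)

    near = dsig(p.k11 * (l - p.r11), p.k11) - dsig(p.k12 * (p.r12 - l), p.k12)
    far = dsig(p.k21 * (l - p.r21), p.k21) - dsig(p.k22 * (p.r22 - l), p.k22)
    walls = (-p.kw / np.sinh(p.kw * (l - p.lmin)) ** 2
             + p.kw / np.sinh(p.kw * (p.lmax - l)) ** 2)
    return p.V0 * (p.b * (near + far) + walls)


def v_in_eval(l, p: PotentialParams):
    """V_in(l) with the offset applied; domain error outside (lmin, lmax)."""
    arr = np.asarray(l, dtype=float)
    if np.any(arr <= p.lmin) or np.any(arr >= p.lmax):
        raise ValueError("edge length outside the potential domain (lmin, lmax)")
    out = _v_in_raw(arr, p) + p.vprime
    return float(out) if np.isscalar(l) else out


def v_in_deriv(l, p: PotentialParams):
    arr = np.asarray(l, dtype=float)
    if np.any(arr <= p.lmin) or np.any(arr >= p.lmax):
        raise ValueError("edge length outside the potential domain (lmin, lmax)")
    out = _v_in_raw_deriv(arr, p)
    return float(out) if np.isscalar(l) else out


def internal_energy_vertex(mesh: TriMesh, p: PotentialParams) -> np.ndarray:
    """E_in(i) = sum over 1-ring of V_in / 2 (each edge shared evenly)."""
    vin = v_in_eval(mesh.edge_lengths(), p)
    e = np.zeros(mesh.n_vertices)
    _scat1(e, mesh.edges[:, 0], 0.5 * vin)
    _scat1(e, mesh.edges[:, 1], 0.5 * vin)
    return e


def internal_energy_total(mesh: TriMesh, p: PotentialParams) -> float:
    return float(v_in_eval(mesh.edge_lengths(), p).sum())


def internal_force(mesh: TriMesh, p: PotentialParams) -> np.ndarray:
    """Minus gradient of the full edge-sum internal energy; pairwise, so the
    forces sum to zero exactly."""
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    d = mesh.positions[i] - mesh.positions[j]
    length = np.linalg.norm(d, axis=1)
    dv = v_in_deriv(length, p)
    pair = -(dv / length)[:, None] * d
    f = np.zeros_like(mesh.positions)
    _scat3(f, i, pair)
    _scat3(f, j, -pair)
    return f


# =========================================================================
# Helfrich bending
# =========================================================================


def helfrich_vertex(mesh: TriMesh, kappa: float, C0: float = 0.0) -> np.ndarray:
    """Per-vertex discrete Helfrich energy H(i) = kappa/2 A_v (2|C| - C0)^2."""
    geo = triangle_geometry(mesh)
    if np.any(geo["area"] <= 0.0):
        raise MeshError("degenerate triangle in Helfrich evaluation")
    T = cot_laplacian_vector(mesh, geo)
    av = np.zeros(mesh.n_vertices)
    _scat1(av, mesh.faces, geo["mixed"])
    absK = np.linalg.norm(T, axis=1) / (2.0 * av)  # = 2|C|
    return 0.5 * kappa * av * (absK - C0) ** 2


def helfrich_total(mesh: TriMesh, kappa: float, C0: float = 0.0) -> float:
    return float(helfrich_vertex(mesh, kappa, C0).sum())


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis plumbing overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _face_area_gradients(P: np.ndarray, n2A: np.ndarray):
    """(F,3,3) gradient of triangle area w.r.t. each corner position."""
    A2 = np.linalg.norm(n2A, axis=1)
    nhat = n2A / A2[:, None]
    g = np.empty_like(P)
    g[:, 0, :] = 0.5 * _cross(nhat, P[:, 2, :] - P[:, 1, :])
    g[:, 1, :] = 0.5 * _cross(nhat, P[:, 0, :] - P[:, 2, :])
    g[:, 2, :] = 0.5 * _cross(nhat, P[:, 1, :] - P[:, 0, :])
    return g


def _scatter_face_grad(mesh, GF: np.ndarray) -> np.ndarray:
    """Collapse per-face-corner gradient contributions (F,3,3) onto vertices."""
    G = np.empty_like(mesh.positions)
    idx = mesh.faces.ravel()
    n = mesh.n_vertices
    flat = GF.reshape(-1, 3)
    G[:, 0] = np.bincount(idx, flat[:, 0], minlength=n)
    G[:, 1] = np.bincount(idx, flat[:, 1], minlength=n)
    G[:, 2] = np.bincount(idx, flat[:, 2], minlength=n)
    return G


def _mixed_area_gradient_accumulate(mesh, geo, adjoint, GF):
    """Accumulate sum_i adjoint[i] * d(A_v(i))/dr into the per-face-corner
    gradient array GF (F,3,3), in place.

    The mixed rule is differentiated branch by branch: exact Voronoi shares
    for non-obtuse faces, area/2 and area/4 clamps for obtuse ones.
    """
    F = mesh.faces
    P = mesh.positions[F]
    area = geo["area"]
    cot = geo["cot"]
    l2 = geo["l2"]
    gradA = _face_area_gradients(P, geo["normal2A"])
    adj = adjoint[F]  # (F, 3)
    obtuse = cot < 0.0
    is_ob = obtuse.any(axis=1)
    reg = ~is_ob

    if np.any(is_ob):
        w = np.full((int(is_ob.sum()), 3), 0.25)
        w[obtuse[is_ob]] = 0.5
        coeff = np.einsum("fk,fk->f", adj[is_ob], w)  # (Fo,)
        GF[is_ob] += coeff[:, None, None] * gradA[is_ob]

    if np.any(reg):
        Pr = P[reg]
        Ar = area[reg]
        cr = cot[reg]
        l2r = l2[reg]
        gAr = gradA[reg]
        adjr = adj[reg]
        inv2A = 1.0 / (2.0 * Ar)
        GFr = np.zeros_like(Pr)
        # share at corner k = (l2[k+1]*cot[k+1] + l2[k+2]*cot[k+2]) / 8
        # iterate over the two (edge, opposite-corner) terms of each share
        for k in range(3):
            a, b = (k + 1) % 3, (k + 2) % 3
            for m, other in ((a, b), (b, a)):
                # term = l2[m] * cot[m] / 8, edge opposite corner m is
                # (k, other); adjoint weight is adjr[:, k]
                wgt = adjr[:, k] / 8.0
                cm = cr[:, m]
                # d l2[m]: edge between corners k and other
                dkm = 2.0 * (Pr[:, k, :] - Pr[:, other, :])
                GFr[:, k] += (wgt * cm)[:, None] * dkm
                GFr[:, other] -= (wgt * cm)[:, None] * dkm
                # d cot[m] = d d_m/(2A) - cot[m] * dA / A, with
                # d_m = (P_u - P_m).(P_v - P_m), u,v the other two corners
                u, v = (m + 1) % 3, (m + 2) % 3
                coef = wgt * l2r[:, m]
                GFr[:, u] += (coef * inv2A)[:, None] * (Pr[:, v, :] - Pr[:, m, :])
                GFr[:, v] += (coef * inv2A)[:, None] * (Pr[:, u, :] - Pr[:, m, :])
                GFr[:, m] += ((coef * inv2A)[:, None]
                              * (2.0 * Pr[:, m, :] - Pr[:, u, :] - Pr[:, v, :]))
                GFr -= (coef * cm / Ar)[:, None, None] * gAr
        GF[reg] += GFr


def helfrich_gradient(mesh: TriMesh, kappa: float, C0: float = 0.0,
                      vertex_weight: np.ndarray | None = None,
                      geo=None) -> np.ndarray:
    """Exact gradient of total discrete Helfrich energy w.r.t. positions.

    Because the cot weights and mixed areas entering H(i) are star-local,
    the 1-ring force stencil is the complete gradient, not a truncation.

    ``vertex_weight`` w_i turns the objective into sum_i w_i H(i), which mesh
    fixtures use to equalize the per-vertex energy (w_i = dJ/dH_i for an
    arbitrary smooth functional J of the per-vertex energies).
    """
    if geo is None:
        geo = triangle_geometry(mesh)
    if np.any(geo["area"] <= 0.0):
        raise MeshError("degenerate triangle in bending gradient")
    F = mesh.faces
    P = mesh.positions[F]
    T = cot_laplacian_vector(mesh, geo)
    av = np.zeros(mesh.n_vertices)
    _scat1(av, F, geo["mixed"])
    normT = np.linalg.norm(T, axis=1)
    absK = normT / (2.0 * av)
    # adjoints: lam = dH/dT (vector), beta = dH/dA_v (scalar)
    with np.errstate(invalid="ignore", divide="ignore"):
        That = np.where(normT[:, None] > 0, T / np.where(normT == 0, 1, normT)[:, None], 0.0)
    lam = 0.5 * kappa * (absK - C0)[:, None] * That
    beta = -0.5 * kappa * (absK ** 2 - C0 ** 2)
    if vertex_weight is not None:
        lam = lam * vertex_weight[:, None]
        beta = beta * vertex_weight

    area = geo["area"]
    cot = geo["cot"]
    gradA = _face_area_gradients(P, geo["normal2A"])
    inv2A = 1.0 / (2.0 * area)
    lamF = lam[F]  # (F, 3, 3)
    GF = np.zeros_like(P)
    # T-path: T_va += cot_k (r_a - r_b), T_vb -= cot_k (r_a - r_b)
    for k in range(3):
        a, b = (k + 1) % 3, (k + 2) % 3
        d_ab = P[:, a, :] - P[:, b, :]
        lam_diff = lamF[:, a, :] - lamF[:, b, :]
        ck = cot[:, k]
        g_k = np.einsum("fx,fx->f", d_ab, lam_diff)
        # c_k * d(g_k)
        GF[:, a] += ck[:, None] * lam_diff
        GF[:, b] -= ck[:, None] * lam_diff
        # g_k * d(c_k); c_k = d_k/(2A), d_k = (P_a - P_k).(P_b - P_k)
        GF[:, a] += (g_k * inv2A)[:, None] * (P[:, b, :] - P[:, k, :])
        GF[:, b] += (g_k * inv2A)[:, None] * (P[:, a, :] - P[:, k, :])
        GF[:, k] += ((g_k * inv2A)[:, None]
                     * (2.0 * P[:, k, :] - P[:, a, :] - P[:, b, :]))
        GF -= (g_k * ck / area)[:, None, None] * gradA
    # mixed-area path
    _mixed_area_gradient_accumulate(mesh, geo, beta, GF)
    return _scatter_face_grad(mesh, GF)


def bending_force(mesh: TriMesh, kappa: float, C0: float = 0.0,
                  geo=None) -> np.ndarray:
    """f_b = -grad of total Helfrich energy (per-vertex 3-vectors)."""
    return -helfrich_gradient(mesh, kappa, C0, geo=geo)


# =========================================================================
# Volume / area penalties and local tension
# =========================================================================


def volume_energy(mesh: TriMesh, k_v: float, V0_target: float) -> float:
    if V0_target <= 0:
        raise ValueError("V0_target must be positive")
    V = enclosed_volume(mesh)
    return k_v * (V - V0_target) ** 2 / V0_target


def area_energy(mesh: TriMesh, k_s: float, S0_target: float) -> float:
    if S0_target <= 0:
        raise ValueError("S0_target must be positive")
    S = float(triangle_geometry(mesh)["area"].sum())
    return k_s * (S - S0_target) ** 2 / S0_target


def volume_gradient(mesh: TriMesh) -> np.ndarray:
    """Gradient of the signed enclosed volume w.r.t. positions."""
    F = mesh.faces
    P = mesh.positions[F]
    GF = np.empty_like(P)
    GF[:, 0] = _cross(P[:, 1, :], P[:, 2, :]) / 6.0
    GF[:, 1] = _cross(P[:, 2, :], P[:, 0, :]) / 6.0
    GF[:, 2] = _cross(P[:, 0, :], P[:, 1, :]) / 6.0
    return _scatter_face_grad(mesh, GF)


def area_gradient(mesh: TriMesh, geo=None) -> np.ndarray:
    if geo is None:
        geo = triangle_geometry(mesh)
    gA = _face_area_gradients(mesh.positions[mesh.faces], geo["normal2A"])
    return _scatter_face_grad(mesh, gA)


def local_tension_energy(mesh: TriMesh, k_s_loc: float, s0: np.ndarray,
                         rho0: np.ndarray | float = 1.0) -> float:
    """E_s' = k Σ_i (s_i/ρ_i − s0_i/ρ0_i)² / (s0_i/ρ0_i), with s_i = A_v(i)."""
    if np.any(mesh.density <= 0):
        raise ValueError("non-positive lipid density")
    geo = triangle_geometry(mesh)
    av = np.zeros(mesh.n_vertices)
    _scat1(av, mesh.faces, geo["mixed"])
    ref = np.asarray(s0) / np.asarray(rho0)
    return float(k_s_loc * np.sum((av / mesh.density - ref) ** 2 / ref))


def local_tension_gradient(mesh: TriMesh, k_s_loc: float, s0: np.ndarray,
                           rho0: np.ndarray | float = 1.0,
                           geo=None) -> np.ndarray:
    if geo is None:
        geo = triangle_geometry(mesh)
    av = np.zeros(mesh.n_vertices)
    _scat1(av, mesh.faces, geo["mixed"])
    ref = np.asarray(s0) / np.asarray(rho0)
    adj = 2.0 * k_s_loc * (av / mesh.density - ref) / (ref * mesh.density)
    GF = np.zeros_like(mesh.positions[mesh.faces])
    _mixed_area_gradient_accumulate(mesh, geo, adj, GF)
    return _scatter_face_grad(mesh, GF)


# =========================================================================
# External control points
# =========================================================================


@dataclasses.dataclass
class ControlPointSet:
    """Fixed external points with Hookean coupling to target vertices.

    Each point attracts its target vertex and the target's *current* 1-ring
    with stiffness ``k_ex``; ``active`` holds per-point (start, stop) step
    ranges (stop = None means open-ended).
    """

    points: np.ndarray                       # (P, 3)
    targets: np.ndarray                      # (P,) vertex ids
    k_ex: float = 20.0
    active: list | None = None               # per point (start, stop) or None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.targets = np.atleast_1d(np.asarray(self.targets, dtype=np.int64))
        if len(self.points) != len(self.targets):
            raise ValueError("points and targets length mismatch")
        if self.active is None:
            self.active = [None] * len(self.targets)

    def is_active(self, k: int, step: int | None) -> bool:
        window = self.active[k]
        if window is None or step is None:
            return True
        start, stop = window
        return step >= start and (stop is None or step < stop)

    def remap_target(self, old: int, new: int) -> None:
        """Redirect control points after a merge removed their target vertex."""
        self.targets[self.targets == old] = new

    def shift_indices(self, removed: int) -> None:
        """Account for vertex reindexing after a removal."""
        if np.any(self.targets == removed):
            raise ValueError("control point targets a removed vertex; remap first")
        self.targets[self.targets > removed] -= 1


def external_spring_energy(mesh: TriMesh, cps: ControlPointSet,
                           step: int | None = None) -> float:
    e = 0.0
    for k in range(len(cps.targets)):
        if not cps.is_active(k, step):
            continue
        v = int(cps.targets[k])
        if v >= mesh.n_vertices:
            raise MeshError("stale control-point target id")
        coupled = np.concatenate([[v], mesh.one_ring(v)])
        d = mesh.positions[coupled] - cps.points[k]
        e += 0.5 * cps.k_ex * float(np.sum(d * d))
    return e


def external_spring_force(mesh: TriMesh, cps: ControlPointSet,
                          step: int | None = None) -> np.ndarray:
    f = np.zeros_like(mesh.positions)
    for k in range(len(cps.targets)):
        if not cps.is_active(k, step):
            continue
        v = int(cps.targets[k])
        if v >= mesh.n_vertices:
            raise MeshError("stale control-point target id")
        coupled = np.concatenate([[v], mesh.one_ring(v)])
        f[coupled] -= cps.k_ex * (mesh.positions[coupled] - cps.points[k])
    return f


# =========================================================================
# Totals
# =========================================================================


@dataclasses.dataclass
class EnergyBreakdown:
    E_in: float
    H: float
    E_v: float
    E_s: float
    E_ex: float

    @property
    def total(self) -> float:
        return self.E_in + self.H + self.E_v + self.E_s + self.E_ex


def ring_average(mesh: TriMesh, field: np.ndarray) -> np.ndarray:
    """Average a per-vertex (vector) field over {i} and its 1-ring."""
    acc = field.copy()
    cnt = np.ones(mesh.n_vertices)
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    _scat3(acc, i, field[j])
    _scat3(acc, j, field[i])
    cnt += np.bincount(i, minlength=len(cnt))
    cnt += np.bincount(j, minlength=len(cnt))
    return acc / cnt[:, None]


def constraint_gradient(mesh: TriMesh, cfg, geo=None) -> np.ndarray:
    """Raw gradient of E_v + (E_s or E_s'), before 1-ring averaging."""
    if geo is None:
        geo = triangle_geometry(mesh)
    G = np.zeros_like(mesh.positions)
    if cfg.k_v:
        V = enclosed_volume(mesh)
        G += (2.0 * cfg.k_v * (V - cfg.V0_target) / cfg.V0_target) * volume_gradient(mesh)
    if getattr(cfg, "use_local_tension", False):
        G += local_tension_gradient(mesh, cfg.k_s_loc, cfg.s0_field,
                                    cfg.rho0_field, geo=geo)
    elif cfg.k_s:
        S = float(geo["area"].sum())
        G += (2.0 * cfg.k_s * (S - cfg.S0_target) / cfg.S0_target) * area_gradient(mesh, geo)
    return G


def total_force(mesh: TriMesh, cfg, cps: ControlPointSet | None = None,
                noise: np.ndarray | None = None,
                step: int | None = None) -> np.ndarray:
    """f_tot = f_in + f_b + xi + <-(grad E_v + grad E_s)>_1-ring + f_ex.

    The volume/area constraint gradient at each vertex is replaced by the
    mean of the raw gradients over the vertex and its 1-ring, which smooths
    the penalty forces for numerical stability.
    """
    geo = triangle_geometry(mesh)
    if getattr(cfg, "geo_mode", False):
        f = np.zeros_like(mesh.positions)  # baseline: V_in removed
    else:
        f = internal_force(mesh, cfg.potential)
    if cfg.kappa:
        f += bending_force(mesh, cfg.kappa, cfg.C0, geo=geo)
    f -= ring_average(mesh, constraint_gradient(mesh, cfg, geo=geo))
    if cps is not None and len(cps.targets):
        f += external_spring_force(mesh, cps, step)
    if noise is not None:
        f = f + noise
    return f
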