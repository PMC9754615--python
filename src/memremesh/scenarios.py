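"""Reproducible simulation scenarios and their measurement procedures.

Each driver runs the full loop — adaptive Langevin dynamics, barrier-crossing
detection, split/merge remeshing, density bookkeeping — for one of the study
setups: red-blood-cell shape relaxation, vesicle fusion (with the
free-energy vs geometry-baseline comparison), control-point-driven
protrusions/invaginations, and the two-tether pulling experiment with
diffusion barriers and a membrane reservoir.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .adaptive_dynamics import build_segmented_potential, langevin_step
from .energetics import ControlPointSet
from .io_cli import SimulationConfig, icosphere_with_edge, rng_streams
from .lipid_tension import diffuse_density, make_barrier
from .remeshing import RemeshEvent, process_barrier_crossings
from .trimesh_core import (
    TriMesh,
    build_fused_spheres,
    enclosed_volume,
    mixed_voronoi_area,
    surface_area,
    validate_mesh,
)

#: iteration counts of the full-scale study setups (scaled down in tests)
FULL_ITERATIONS = {"rbc": 50_000, "fusion": 50_000, "comparison": 20_000,
                   "filopodium": 20_000, "lamellipodium": 20_000,
                   "invagination": 20_000}
N_TETHER_SEEDS = 8


@dataclasses.dataclass
class ScenarioResult:
    mesh: TriMesh
    ledger: list            # event rows (dicts)
    records: list           # StepRecord stream (possibly thinned)
    energies: list
    config: SimulationConfig
    frames: list = dataclasses.field(default_factory=list)


def _event_row(ev: RemeshEvent, mesh: TriMesh, step: int) -> dict:
    centroid = mesh.positions.mean(axis=0)
    rel = ev.position - centroid
    return {"step": step, "kind": ev.kind, "outcome": ev.outcome,
            "x": float(ev.position[0]), "y": float(ev.position[1]),
            "z": float(ev.position[2]),
            "dx": float(rel[0]), "dy": float(rel[1]), "dz": float(rel[2]),
            "r_centroid": float(np.linalg.norm(rel)),
            "option": ev.option_index}


def _split_s0(cfg: SimulationConfig, ev: RemeshEvent) -> None:
    """Keep the local-tension reference fields aligned with the vertex list.

    Reference area s0: a split child interpolates its parents, a merge sums.
    Reference density rho0 follows the same bookkeeping as the live density
    (split: the parents' total shared equally by the three vertices; merge:
    summed), so the reference state stays self-consistent.
    """
    if cfg.s0_field is None:
        return
    i1, i2 = ev.edge
    s0 = np.asarray(cfg.s0_field, dtype=float)
    rho0 = cfg.rho0_field
    track_rho = isinstance(rho0, np.ndarray)
    if ev.kind == "split":
        cfg.s0_field = np.append(s0, 0.5 * (s0[i1] + s0[i2]))
        if track_rho:
            share = (rho0[i1] + rho0[i2]) / 3.0
            rho0 = np.append(rho0, share)
            rho0[i1] = rho0[i2] = share
            cfg.rho0_field = rho0
    else:
        s0[i1] = s0[i1] + s0[i2]
        cfg.s0_field = np.delete(s0, i2)
        if track_rho:
            rho0 = rho0.copy()
            rho0[i1] = rho0[i1] + rho0[i2]
            cfg.rho0_field = np.delete(rho0, i2)


def simulate(mesh: TriMesh, cfg: SimulationConfig, n_steps: int,
             cps: ControlPointSet | None = None, seed: int = 0,
             barrier_band=None, permeable_fraction: float = 1.0,
             record_energy_every: int = 0, record_segments: bool = False,
             frame_every: int = 0, max_events_per_step: int = 20,
             callbacks: list | None = None) -> ScenarioResult:
    """Run the main loop for ``n_steps`` adaptive Langevin iterations.

    After every successful remeshing event the density master equation runs
    for cfg.n_d iterations; when a ``barrier_band`` predicate is given the
    barrier mask is rebuilt from the current mesh with the configured
    permeable fraction before diffusing.
    """
    streams = rng_streams(seed, ("dynamics", "remesh", "barrier"))
    sp = build_segmented_potential(cfg.potential)
    t = 0.0
    cooldown: dict = {}
    ledger: list[dict] = []
    records: list = []
    energies: list = []
    frames: list = []
    for step in range(n_steps):
        rec = langevin_step(mesh, cfg, cps, sp, streams["dynamics"], step, t,
                            record_segments=record_segments)
        t = rec.t
        if record_segments:
            records.append(rec)
        events = process_barrier_crossings(mesh, cfg, streams["remesh"], step,
                                           cps, max_events=max_events_per_step,
                                           cooldown=cooldown)
        for ev in events:
            ledger.append(_event_row(ev, mesh, step))
            if ev.success:
                if cfg.use_local_tension:
                    _split_s0(cfg, ev)
                mask = None
                if barrier_band is not None:
                    mask = make_barrier(mesh, barrier_band, permeable_fraction,
                                        streams["barrier"])
                diffuse_density(mesh, cfg.k_d, cfg.n_d, mask)
        if record_energy_every and step % record_energy_every == 0:
            energies.append((step, _total_energy(mesh, cfg, cps, step)))
        if frame_every and step % frame_every == 0:
            frames.append(mesh.copy())
        if callbacks:
            for cb in callbacks:
                cb(step, mesh, cfg)
    return ScenarioResult(mesh=mesh, ledger=ledger, records=records,
                          energies=energies, config=cfg, frames=frames)


def _total_energy(mesh, cfg, cps, step) -> float:
    from . import energetics as en
    e = en.internal_energy_total(mesh, cfg.potential) if not cfg.geo_mode else 0.0
    e += en.helfrich_total(mesh, cfg.kappa, cfg.C0)
    e += en.volume_energy(mesh, cfg.k_v, cfg.V0_target)
    if cfg.use_local_tension:
        e += en.local_tension_energy(mesh, cfg.k_s_loc, cfg.s0_field,
                                     cfg.rho0_field)
    else:
        e += en.area_energy(mesh, cfg.k_s, cfg.S0_target)
    if cps is not None:
        e += en.external_spring_energy(mesh, cps, step)
    return float(e)


# ---------------------------------------------------------------------------
# spontaneous morphodynamics
# ---------------------------------------------------------------------------


def run_rbc(n_steps: int, subdivisions: int = 3, seed: int = 0,
            cfg: SimulationConfig | None = None, **sim_kw) -> ScenarioResult:
    """Sphere with the target volume reduced to 60%: relaxes to a biconcave
    discocyte while the area target holds the initial sphere's area."""
    mesh = icosphere_with_edge(subdivisions, 1.0)
    cfg = (cfg or SimulationConfig()).replace(
        V0_target=0.6 * enclosed_volume(mesh),
        S0_target=surface_area(mesh))
    res = simulate(mesh, cfg, n_steps, seed=seed, **sim_kw)
    if not validate_mesh(res.mesh):
        raise RuntimeError("mesh invariant violated in RBC run")
    return res


def run_fusion(n_steps: int, subdivisions: int = 3, seed: int = 0,
               mode: str = "FE", cfg: SimulationConfig | None = None,
               **sim_kw) -> ScenarioResult:
    """Two bridged vesicles relaxing into one; V0 and S0 are the totals of
    the two spheres.  ``mode`` selects the free-energy ("FE") or
    geometry-baseline ("Geo") remesher."""
    radius = {2: 3.8, 3: 7.6}.get(subdivisions)
    if radius is None:
        probe = icosphere_with_edge(subdivisions, 1.0)
        radius = float(np.linalg.norm(probe.positions, axis=1).mean())
    mesh = build_fused_spheres(subdivisions, radius=radius)
    sphere_v = enclosed_volume(icosphere_with_edge(subdivisions, 1.0))
    sphere_s = surface_area(icosphere_with_edge(subdivisions, 1.0))
    cfg = (cfg or SimulationConfig()).replace(
        V0_target=2.0 * sphere_v, S0_target=2.0 * sphere_s,
        geo_mode=(mode.lower() == "geo"))
    res = simulate(mesh, cfg, n_steps, seed=seed, **sim_kw)
    if not validate_mesh(res.mesh):
        raise RuntimeError("mesh invariant violated in fusion run")
    return res


def compare_remeshing(fe_ledger: list, geo_ledger: list) -> dict:
    """Event-count and spatial-spread ratios between Geo and FE ledgers.

    Only successful events count as remeshing operations; the spatial spread
    is the standard deviation of the event coordinates, taken about the mesh
    centroid at event time (translation invariant) and pooled over the three
    axes (rms of the per-axis standard deviations).
    """
    def stats(ledger):
        rows = [r for r in ledger if r["outcome"] == "success"]
        if not rows:
            raise ValueError("ledger holds no successful events")
        xyz = np.array([[row["dx"], row["dy"], row["dz"]] for row in rows])
        return len(rows), float(np.sqrt(xyz.var(axis=0).mean()))

    n_fe, s_fe = stats(fe_ledger)
    n_geo, s_geo = stats(geo_ledger)
    return {"count_ratio": n_geo / n_fe,
            "sigma_ratio": s_geo / s_fe if s_fe > 0 else np.inf,
            "n_fe": n_fe, "n_geo": n_geo,
            "sigma_fe": s_fe, "sigma_geo": s_geo}


# ---------------------------------------------------------------------------
# morphodynamics under external forces
# ---------------------------------------------------------------------------


def _nearest_vertex(mesh: TriMesh, point) -> int:
    return int(np.argmin(np.linalg.norm(mesh.positions - np.asarray(point),
                                        axis=1)))


def _holder_points(mesh: TriMesh, exclude_direction, n: int = 4,
                   k_ex: float = 20.0):
    """Control points pinning the cell body, away from the pulled region."""
    d = np.asarray(exclude_direction, dtype=float)
    d /= np.linalg.norm(d)
    scores = mesh.positions @ d
    order = np.argsort(scores)  # most opposite first
    pts, tgts = [], []
    for idx in order[:n]:
        pts.append(mesh.positions[idx].copy())
        tgts.append(int(idx))
    return pts, tgts


def run_protrusion(kind: str, n_steps: int, subdivisions: int = 3,
                   seed: int = 0, cfg: SimulationConfig | None = None,
                   pull_distance: float = 4.0, **sim_kw) -> ScenarioResult:
    """Filopodia (3 tip points), a lamellipodial rim (extended at half run)
    or an invagination (a point 1/3 into the cell), each with holders."""
    mesh = icosphere_with_edge(subdivisions, 1.0)
    R = float(np.linalg.norm(mesh.positions, axis=1).mean())
    cfg = (cfg or SimulationConfig()).replace(
        V0_target=enclosed_volume(mesh), S0_target=1.3 * surface_area(mesh))
    pts, tgts, windows = [], [], []
    if kind == "filopodium":
        dirs = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        for d in dirs:
            pts.append(d * (R + pull_distance))
            tgts.append(_nearest_vertex(mesh, d * R))
            windows.append(None)
        hold_dir = -dirs.sum(axis=0)
    elif kind == "lamellipodium":
        n_rim = 6
        for k in range(n_rim):
            th = np.pi / 8 * (k - (n_rim - 1) / 2)
            d = np.array([np.cos(th), np.sin(th), 0.0])
            pts.append(d * (R + 0.5 * pull_distance))
            tgts.append(_nearest_vertex(mesh, d * R))
            windows.append((0, n_steps // 2))
            # extended rim for the second half
            pts.append(d * (R + pull_distance))
            tgts.append(tgts[-1])
            windows.append((n_steps // 2, None))
        hold_dir = np.array([-1.0, 0, 0])
    elif kind == "invagination":
        d = np.array([1.0, 0, 0])
        pts.append(d * (R - R / 3.0 - 0.0))
        tgts.append(_nearest_vertex(mesh, d * R))
        windows.append(None)
        hold_dir = -d
    else:
        raise ValueError(f"unknown protrusion kind {kind!r}")
    hpts, htgts = _holder_points(mesh, hold_dir)
    pts += hpts
    tgts += htgts
    windows += [None] * len(hpts)
    cps = ControlPointSet(np.array(pts), np.array(tgts), k_ex=cfg.k_ex,
                          active=windows)
    res = simulate(mesh, cfg, n_steps, cps=cps, seed=seed, **sim_kw)
    if not validate_mesh(res.mesh):
        raise RuntimeError(f"mesh invariant violated in {kind} run")
    return res


# ---------------------------------------------------------------------------
# tether pulling
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TetherMetrics:
    times: np.ndarray
    left_radius: np.ndarray     # normalized to the pull-start morphology
    right_radius: np.ndarray
    left_fit: np.ndarray        # degree-4 polynomial coefficients
    right_fit: np.ndarray
    left_last: float
    right_last: float


def measure_tether_radius(mesh: TriMesh, tether_axis, station: float,
                          half_width: float = 0.75) -> float:
    """Mean distance from the tether axis of the vertices in the axial band
    station +- half_width.

    The axis passes through the origin of the lab frame, which the holder
    control points keep fixed; an axial station is therefore an absolute
    coordinate (a centroid-relative station would slide along the tether as
    the pull displaces the center of mass).
    """
    axis = np.asarray(tether_axis, dtype=float)
    axis /= np.linalg.norm(axis)
    axial = mesh.positions @ axis
    band = np.abs(axial - station) < half_width
    if not np.any(band):
        raise ValueError("no vertices in the measurement band")
    radial = mesh.positions[band] - np.outer(axial[band], axis)
    return float(np.linalg.norm(radial, axis=1).mean())


def fit_radius_polynomial(times, radii) -> tuple[np.ndarray, float]:
    """Least-squares degree-4 fit; returns (coefficients, last fitted value)."""
    times = np.asarray(times, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(times) < 5:
        raise ValueError("need at least 5 samples for a degree-4 fit")
    coeffs = np.polyfit(times, radii, deg=4)
    return coeffs, float(np.polyval(coeffs, times[-1]))


def run_tether_experiment(condition: str, k_d: float, seed: int,
                          subdivisions: int = 2,
                          init_steps: int = 1500, pull_steps: int = 1500,
                          pull_distance: float = 2.0,
                          sample_every: int = 100,
                          cfg: SimulationConfig | None = None) -> TetherMetrics:
    """Two tethers pulled from a sphere; the left one is pulled further.

    ``condition`` is one of naive / barrier / reservoir: the naive membrane
    diffuses freely, the barrier blocks all but 6% of the edges in a band
    around the cell equator (x ~ 0), and the reservoir additionally grants
    33% excess reference area.  Returns per-frame normalized tether radii
    during the extra pull, with their fourth-order polynomial fits.
    """
    if condition not in ("naive", "barrier", "reservoir"):
        raise ValueError(f"unknown condition {condition!r}")
    mesh = icosphere_with_edge(subdivisions, 1.0)
    R = float(np.linalg.norm(mesh.positions, axis=1).mean())
    cfg = (cfg or SimulationConfig()).replace(
        k_d=k_d, V0_target=enclosed_volume(mesh),
        S0_target=surface_area(mesh))
    tip = R + 2.5
    pts = [np.array([-tip, 0.0, 0.0]), np.array([tip, 0.0, 0.0])]
    tgts = [_nearest_vertex(mesh, [-R, 0, 0]), _nearest_vertex(mesh, [R, 0, 0])]
    for d in ([0, 1.0, 0], [0, -1.0, 0], [0, 0, 1.0], [0, 0, -1.0]):
        pts.append(np.asarray(d) * R)
        tgts.append(_nearest_vertex(mesh, np.asarray(d) * R))
    cps = ControlPointSet(np.array(pts), np.array(tgts), k_ex=cfg.k_ex)

    # phase 1: initialize the two tethers under the global tension term
    simulate(mesh, cfg, init_steps, cps=cps, seed=seed)

    # switch to the density-weighted local tension with the pull-start
    # morphology as reference
    cfg.use_local_tension = True
    cfg.s0_field = mixed_voronoi_area(mesh)
    cfg.rho0_field = mesh.density.copy()
    if condition == "reservoir":
        from .lipid_tension import apply_reservoir
        apply_reservoir(cfg)
    band = None
    permeable = 1.0
    if condition in ("barrier", "reservoir"):
        width = 0.6
        band = lambda m: abs(m[0]) < width  # noqa: E731
        permeable = 0.06

    station = 0.5 * (R + tip)
    r_left0 = measure_tether_radius(mesh, [-1, 0, 0], station)
    r_right0 = measure_tether_radius(mesh, [1, 0, 0], station)

    times, lefts, rights = [], [], []
    left_cp = 0  # index of the left control point
    start = cps.points[left_cp, 0]
    for chunk in range(0, pull_steps, sample_every):
        frac = (chunk + sample_every) / pull_steps
        cps.points[left_cp, 0] = start - frac * pull_distance
        simulate(mesh, cfg, sample_every, cps=cps, seed=seed * 7919 + chunk,
                 barrier_band=band, permeable_fraction=permeable)
        times.append(chunk + sample_every)
        lefts.append(measure_tether_radius(mesh, [-1, 0, 0], station) / r_left0)
        rights.append(measure_tether_radius(mesh, [1, 0, 0], station) / r_right0)
    lf, ll = fit_radius_polynomial(times, lefts)
    rf, rl = fit_radius_polynomial(times, rights)
    return TetherMetrics(times=np.array(times), left_radius=np.array(lefts),
                         right_radius=np.array(rights), left_fit=lf,
                         right_fit=rf, left_last=ll, right_last=rl)


def tether_kd_scan(conditions=("naive", "barrier", "reservoir"),
                   k_d_values=None, n_seeds: int = N_TETHER_SEEDS,
                   **run_kw) -> dict:
    """Scan k_d for each membrane condition; the ensemble-mean last fitted
    right-tether radius is the mechanical-coupling readout."""
    if k_d_values is None:
        k_d_values = np.geomspace(0.025, 0.25, 6)
    out: dict = {}
    for cond in conditions:
        rows = []
        for kd in k_d_values:
            vals = []
            for s in range(n_seeds):
                m = run_tether_experiment(cond, float(kd), seed=s, **run_kw)
                vals.append(m.right_last)
            rows.append((float(kd), float(np.mean(vals)), float(np.std(vals))))
        out[cond] = rows
    return out


# ---------------------------------------------------------------------------
# mesh-error analysis
# ---------------------------------------------------------------------------


def mesh_error_map(mesh: TriMesh, kappa: float = 1.0) -> dict:
    """Per-vertex percentage deviation of the discrete Helfrich energy from
    the exact per-vertex share 8 pi kappa / N of an ideal sphere."""
    from .energetics import helfrich_vertex
    H = helfrich_vertex(mesh, kappa)
    exact = 8.0 * np.pi * kappa / mesh.n_vertices
    dH = (H - exact) / exact * 100.0
    hist, bin_edges = np.histogram(dH, bins=40)
    return {"dH": dH, "hist": hist, "bin_edges": bin_edges,
            "valences": mesh.valences.copy()}
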