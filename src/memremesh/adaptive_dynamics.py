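"""Piecewise-linear segmentation of V_in and the adaptive-timestep integrator.

The edge-length axis is sampled on a fine grid, split into segments delimited
by the potential's critical points and recursively bisected until each
segment is well approximated by a line.  The overdamped Langevin integrator
then chooses, at every step, the largest time step for which no edge can move
further than the midpoint of a neighboring segment — so edges sweep the
potential one segment at a time and the piecewise-linear substitute stays
faithful where V_in is complex.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import levy_stable

from .energetics import KBT, PotentialParams, total_force, v_in_eval
from .trimesh_core import TriMesh

DT_MAX = 1e-3   # time-step cap (natural time units)
DT_MIN = 1e-9   # floor; clamp events are recorded

# Levy relaxation defaults (used by the remeshing local relaxation)
LEVY_ALPHA = 1.5
LEVY_SCALE = 0.01
LEVY_BIAS = 0.02


def sample_potential(p: PotentialParams) -> np.ndarray:
    """V_in on the grid l = 0, dl, ..., M*dl with M = lmax/dl - 1.

    The last grid point stops one ``dl`` short of ``lmax``, which avoids the
    wall singularity there.
    """
    return v_in_eval(p.grid(), p)


def find_critical_points(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Grid indices of local minima and maxima of the sampled potential.

    The grid start is interior to the potential's domain (lmin < 0), so it
    counts one-sidedly as an extremum; the grid end abuts the wall
    singularity and is excluded.
    """
    v = values
    minima = []
    maxima = []
    if v[0] < v[1]:
        minima.append(0)
    interior_min = np.where((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:]))[0] + 1
    interior_max = np.where((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
    minima.extend(interior_min.tolist())
    maxima.extend(interior_max.tolist())
    return np.array(sorted(minima)), np.array(sorted(maxima))


def _linear_fit_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(R^2, residual sigma) of the least-squares line through (x, y)."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx if sxx > 0 else 0.0
    resid = y - (ym + slope * (x - xm))
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sigma = float(np.sqrt(ss_res / n))
    return r2, sigma


@dataclasses.dataclass
class SegmentedPotential:
    """Piecewise-linear substitute for V_in over the sampled grid.

    ``boundaries`` are grid indices n_0 < n_1 < ... < n_Omega; segment
    ``w`` (1-based in the formulas, 0-based here) covers the half-open
    interval (n_w * dl, n_{w+1} * dl].
    """

    values: np.ndarray          # V_in at every grid point
    boundaries: np.ndarray      # grid indices, boundaries[0] == 0
    dl: float
    n_initial_segments: int
    single_point_warnings: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) - 1

    @property
    def boundary_lengths(self) -> np.ndarray:
        return self.boundaries * self.dl

    def segment_of(self, l) -> np.ndarray:
        """0-based segment index for length(s) l; boundary lengths belong to
        the lower-index segment (half-open (n_{w} dl, n_{w+1} dl])."""
        arr = np.atleast_1d(np.asarray(l, dtype=float))
        idx = np.searchsorted(self.boundary_lengths, arr, side="left") - 1
        idx = np.clip(idx, 0, self.n_segments - 1)
        return idx if np.ndim(l) else int(idx[0])

    def eval(self, l):
        """Linear interpolation between the segment-boundary grid values."""
        arr = np.atleast_1d(np.asarray(l, dtype=float))
        lo, hi = self.boundary_lengths[0], self.boundary_lengths[-1]
        if np.any(arr < lo) or np.any(arr > hi):
            raise ValueError("length outside the segmented range")
        out = np.interp(arr, self.boundary_lengths, self.values[self.boundaries])
        return out if np.ndim(l) else float(out[0])


def segment_potential(values: np.ndarray, p: PotentialParams,
                      r2_min: float = 0.5, sigma_factor: float = 0.001,
                      sigma_mode: str = "residual") -> SegmentedPotential:
    """Segment the sampled potential by recursive midpoint bisection.

    Initial segments are delimited by the critical points (grid boundaries
    plus the interior extrema).  A segment is accepted when its linear fit
    has R^2 > ``r2_min`` and the spread criterion sigma < ``sigma_factor *
    V0`` holds; otherwise it is bisected.  ``sigma_mode`` selects whether
    sigma is the std of residuals about the fit (default) or the raw std of
    the values.  Constant-to-machine-precision segments pass the R^2 test by
    convention (the statistic is undefined there).
    """
    M = len(values) - 1
    minima, maxima = find_critical_points(values)
    cps = np.unique(np.concatenate([[0, M], minima, maxima]))
    initial = [(int(cps[k]), int(cps[k + 1])) for k in range(len(cps) - 1)]

    sigma_cap = sigma_factor * p.V0
    flat_tol = 1e-10 * p.V0
    x_all = np.arange(M + 1, dtype=float)

    accepted: list[tuple[int, int]] = []
    warnings = 0
    stack = list(reversed(initial))
    while stack:
        lo, hi = stack.pop()
        y = values[lo:hi + 1]
        if hi - lo <= 1:
            r2, sigma = _linear_fit_stats(x_all[lo:hi + 1], y)
            if not (sigma < sigma_cap):
                warnings += 1
            accepted.append((lo, hi))
            continue
        r2, sigma = _linear_fit_stats(x_all[lo:hi + 1], y)
        if sigma_mode == "raw":
            sigma = float(np.std(y))
        r2_ok = r2 > r2_min or float(np.ptp(y)) < flat_tol
        if r2_ok and sigma < sigma_cap:
            accepted.append((lo, hi))
        else:
            mid = (lo + hi) // 2
            stack.append((mid, hi))
            stack.append((lo, mid))
    accepted.sort()
    boundaries = np.array([accepted[0][0]] + [b for _, b in accepted], dtype=np.int64)
    return SegmentedPotential(values=np.asarray(values, dtype=float),
                              boundaries=boundaries, dl=p.dl,
                              n_initial_segments=len(initial),
                              single_point_warnings=warnings)


def build_segmented_potential(p: PotentialParams, **kw) -> SegmentedPotential:
    return segment_potential(sample_potential(p), p, **kw)


# =========================================================================
# Adaptive time step
# =========================================================================


@dataclasses.dataclass
class StepRecord:
    step: int
    t: float
    dt: float
    limiting_edge: tuple[int, int] | None
    clamped: bool
    start_segments: np.ndarray | None = None
    end_segments: np.ndarray | None = None


def adaptive_timestep(mesh: TriMesh, forces: np.ndarray, sp: SegmentedPotential,
                      mu: float, dt_min: float = DT_MIN,
                      dt_max: float = DT_MAX,
                      displacement_cap: float = 0.05) -> tuple[float, dict]:
    """Largest time step keeping every edge within one segment hop.

    For each edge the candidate end lengths are the midpoints of the two
    neighboring segments; inverting the first-order length update gives a
    forward and a backward candidate time step, of which exactly one is
    positive (they share a denominator).  The global step is the minimum
    over edges, clamped to (dt_min, dt_max].

    ``displacement_cap`` additionally bounds the largest per-vertex move
    (in length units): forces along vertex normals change edge lengths only
    at second order, so the segment rule alone would let a stiff bending or
    penalty force overshoot in that direction.
    """
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    d = mesh.positions[j] - mesh.positions[i]
    length = np.linalg.norm(d, axis=1)
    seg = sp.segment_of(length)
    bl = sp.boundary_lengths
    n_seg = sp.n_segments

    # forward target: midpoint of segment seg+1; backward: midpoint of seg-1
    has_fwd = seg + 1 < n_seg
    has_bwd = seg - 1 >= 0
    tgt_fwd = np.where(has_fwd, 0.5 * (bl[np.minimum(seg + 1, n_seg - 1)]
                                       + bl[np.minimum(seg + 2, n_seg)]), np.nan)
    tgt_bwd = np.where(has_bwd, 0.5 * (bl[np.maximum(seg - 1, 0)]
                                       + bl[np.maximum(seg, 1) - 1]), np.nan)

    denom = 2.0 * mu * np.einsum("ex,ex->e", d, forces[j] - forces[i])
    with np.errstate(divide="ignore", invalid="ignore"):
        dt_fwd = (tgt_fwd ** 2 - length ** 2) / denom
        dt_bwd = (tgt_bwd ** 2 - length ** 2) / denom
    dt_edge = np.where(np.nan_to_num(dt_fwd, nan=-1.0) > 0, dt_fwd, dt_bwd)
    valid = np.isfinite(dt_edge) & (dt_edge > 0)

    fmax = float(np.linalg.norm(forces, axis=1).max())
    dt_disp = displacement_cap / (mu * fmax) if fmax > 0 else np.inf

    info = {"start_segments": seg}
    if not np.any(valid):
        info["limiting_edge"] = None
        info["clamped"] = True
        return min(dt_max, dt_disp), info
    k = int(np.argmin(np.where(valid, dt_edge, np.inf)))
    dt = float(min(dt_edge[k], dt_disp))
    clamped = False
    if dt > dt_max:
        dt, clamped = dt_max, True
    elif dt < dt_min:
        dt, clamped = dt_min, True
    info["limiting_edge"] = (int(i[k]), int(j[k]))
    info["clamped"] = clamped
    return dt, info


def langevin_step(mesh: TriMesh, cfg, cps, sp: SegmentedPotential,
                  rng: np.random.Generator, step: int = 0, t: float = 0.0,
                  record_segments: bool = False) -> StepRecord:
    """One adaptive overdamped Langevin update of all vertex positions.

    The time-averaged stochastic force xi = eps * sqrt(2 mu kBT dt)/(mu dt)
    enters the total force before the final time step is chosen: a
    provisional step from the deterministic forces sets the noise amplitude,
    then the step is re-derived with the noise included and used to move the
    vertices.
    """
    kbt = getattr(cfg, "kbt", KBT)
    mu = cfg.mu
    cap = getattr(cfg, "displacement_cap", 0.05)
    f_det = total_force(mesh, cfg, cps, noise=None, step=step)
    dt, info = adaptive_timestep(mesh, f_det, sp, mu, cfg.dt_min, cfg.dt_max,
                                 displacement_cap=cap)
    if kbt > 0:
        # the time-averaged noise amplitude depends on dt while dt depends
        # on the total force including the noise; iterate the pair to a
        # fixed point (dt shrinks monotonically and the noise displacement
        # ~ sqrt(dt) shrinks with it, so the iteration settles quickly)
        eps = rng.standard_normal(mesh.positions.shape)
        f_tot = f_det
        for _ in range(6):
            xi = eps * np.sqrt(2.0 * mu * kbt * dt) / (mu * dt)
            f_tot = f_det + xi
            dt_new, info = adaptive_timestep(mesh, f_tot, sp, mu,
                                             cfg.dt_min, cfg.dt_max,
                                             displacement_cap=cap)
            dt_new = min(dt_new, dt)
            if dt_new > 0.9 * dt:
                dt = dt_new
                break
            dt = dt_new
        xi = eps * np.sqrt(2.0 * mu * kbt * dt) / (mu * dt)
        f_tot = f_det + xi
    else:
        f_tot = f_det
    start_seg = info["start_segments"] if record_segments else None
    mesh.positions += mu * f_tot * dt
    if not np.all(np.isfinite(mesh.positions)):
        raise FloatingPointError(f"non-finite positions after step {step}")
    end_seg = None
    if record_segments:
        end_seg = sp.segment_of(mesh.edge_lengths())
    return StepRecord(step=step, t=t + dt, dt=dt,
                      limiting_edge=info["limiting_edge"], clamped=info["clamped"],
                      start_segments=start_seg, end_segments=end_seg)


def levy_noise(rng: np.random.Generator, bias_direction: np.ndarray,
               scale: float = LEVY_SCALE, alpha: float = LEVY_ALPHA,
               bias: float = LEVY_BIAS, clip: float = 0.3) -> np.ndarray:
    """Heavy-tailed isotropic displacement plus a deterministic bias.

    Draws per-component symmetric alpha-stable noise (clipped so a single
    tail event cannot eject a vertex from its patch) and adds ``bias`` times
    the given direction.  Used only inside the remeshing local relaxation.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    shape = np.shape(bias_direction)
    if scale == 0:
        draw = np.zeros(shape)
    else:
        draw = scale * levy_stable.rvs(alpha, 0.0, size=int(np.prod(shape)),
                                       random_state=rng).reshape(shape)
        draw = np.clip(draw, -clip, clip)
    return draw + bias * np.asarray(bias_direction, dtype=float)
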