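import numpy as np
import pytest

from conftest import fd_gradient
from memremesh import trimesh_core as tc
from memremesh.energetics import (
    ControlPointSet,
    PotentialParams,
    area_energy,
    area_gradient,
    bending_force,
    external_spring_energy,
    external_spring_force,
    helfrich_gradient,
    helfrich_total,
    helfrich_vertex,
    internal_energy_total,
    internal_energy_vertex,
    internal_force,
    local_tension_energy,
    local_tension_gradient,
    total_force,
    v_in_eval,
    v_in_deriv,
    volume_energy,
    volume_gradient,
)
from memremesh.io_cli import SimulationConfig
from memremesh.trimesh_core import build_icosphere, enclosed_volume, surface_area


# ---------------------------------------------------------------------- V_in


class TestInternalPotential:
    def test_grid_minimum_is_zero(self, table_params):
        vals = v_in_eval(table_params.grid(), table_params)
        assert vals.min() == 0.0
        assert np.all(np.isfinite(vals))

    def test_triple_valley_shape(self, table_params):
        p = table_params
        g = p.grid()
        vals = v_in_eval(g, p)
        minima = [0] if vals[0] < vals[1] else []
        minima += (np.where((vals[1:-1] < vals[:-2]) & (vals[1:-1] < vals[2:]))[0] + 1).tolist()
        maxima = (np.where((vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:]))[0] + 1).tolist()
        assert len(minima) == 3 and len(maxima) == 2
        # valleys near 0, l0 and 2 l0; barriers between them
        assert g[minima[0]] < 0.1
        assert abs(g[minima[1]] - p.l0) < 0.1
        assert abs(g[minima[2]] - 2 * p.l0) < 0.15
        assert p.r11 < g[maxima[0]] < p.r12
        assert p.r21 < g[maxima[1]] < p.r22

    def test_mid_valley_argmin_at_l0(self, table_params):
        p = table_params
        g = p.grid()
        vals = v_in_eval(g, p)
        sel = (g > p.r12) & (g < p.r21)
        assert abs(g[sel][np.argmin(vals[sel])] - p.l0) < 0.02

    def test_barrier_height_order_one_kbt(self, table_params):
        p = table_params
        g = p.grid()
        vals = v_in_eval(g, p)
        sel = (g > p.r12) & (g < p.r21)
        barrier = vals[(g > p.r21) & (g < p.r22)].max() - vals[sel].min()
        assert 0.3 * p.b * p.V0 < barrier < 2.0 * p.b * p.V0

    def test_domain_error_outside_walls(self, table_params):
        with pytest.raises(ValueError):
            v_in_eval(table_params.lmax + 0.01, table_params)
        with pytest.raises(ValueError):
            v_in_eval(table_params.lmin - 0.01, table_params)

    def test_derivative_matches_finite_difference(self, table_params):
        for l in (0.3, 0.95, 1.4, 2.05):
            fd = (v_in_eval(l + 1e-6, table_params) - v_in_eval(l - 1e-6, table_params)) / 2e-6
            assert abs(v_in_deriv(l, table_params) - fd) < 1e-4 * max(abs(fd), 1.0)

    def test_invariant_ordering_enforced(self):
        with pytest.raises(ValueError):
            PotentialParams(l_p=0.5)  # below l0


class TestInternalEnergyAndForce:
    def test_vertex_split_matches_edge_sum(self, membrane_sphere, table_params):
        per_vertex = internal_energy_vertex(membrane_sphere, table_params)
        total = internal_energy_total(membrane_sphere, table_params)
        assert abs(per_vertex.sum() - total) < 1e-12 * max(abs(total), 1.0)

    def test_force_is_minus_gradient(self, membrane_sphere, table_params, rng):
        m = membrane_sphere.copy()
        m.positions += 0.02 * rng.standard_normal(m.positions.shape)
        f = internal_force(m, table_params)
        G = fd_gradient(lambda ms: internal_energy_total(ms, table_params), m)
        assert np.abs(f + G).max() < 1e-4 * np.abs(G).max()

    def test_newtons_third_law(self, membrane_sphere, table_params):
        f = internal_force(membrane_sphere, table_params)
        assert np.abs(f.sum(axis=0)).max() < 1e-8


# ------------------------------------------------------------------ Helfrich


class TestHelfrich:
    def test_sphere_limit_8_pi(self):
        m = build_icosphere(3, radius=1.0)
        assert abs(helfrich_total(m, 1.0) - 8 * np.pi) < 0.02 * 8 * np.pi

    def test_error_decreases_with_refinement(self):
        errs = [abs(helfrich_total(build_icosphere(n), 1.0) - 8 * np.pi)
                for n in (2, 3, 4)]
        assert errs[0] > errs[1] > errs[2]

    def test_linear_in_kappa(self, unit_icosphere_n2):
        assert np.isclose(helfrich_total(unit_icosphere_n2, 2.0),
                          2.0 * helfrich_total(unit_icosphere_n2, 1.0))

    def test_scale_invariance(self, unit_icosphere_n2):
        # the bending energy of a sphere is independent of its radius
        big = tc.TriMesh(unit_icosphere_n2.positions * 7.0, unit_icosphere_n2.faces.copy())
        assert np.isclose(helfrich_total(big, 1.0), helfrich_total(unit_icosphere_n2, 1.0))

    def test_gradient_matches_finite_difference(self, jittered_mesh):
        G = helfrich_gradient(jittered_mesh, 1.0)
        Gfd = fd_gradient(lambda ms: helfrich_total(ms, 1.0), jittered_mesh)
        assert np.abs(G - Gfd).max() < 1e-3 * np.abs(Gfd).max()

    def test_gradient_with_spontaneous_curvature(self, jittered_mesh):
        G = helfrich_gradient(jittered_mesh, 1.0, C0=0.4)
        Gfd = fd_gradient(lambda ms: helfrich_total(ms, 1.0, 0.4), jittered_mesh)
        assert np.abs(G - Gfd).max() < 1e-3 * np.abs(Gfd).max()

    def test_gradient_on_obtuse_mesh(self, jittered_mesh):
        jittered_mesh.positions[:, 0] *= 3.0
        geo = tc.triangle_geometry(jittered_mesh)
        assert np.any(geo["cot"] < 0)  # mixed-area clamp branch exercised
        G = helfrich_gradient(jittered_mesh, 1.0)
        Gfd = fd_gradient(lambda ms: helfrich_total(ms, 1.0), jittered_mesh)
        assert np.abs(G - Gfd).max() < 1e-3 * np.abs(Gfd).max()

    def test_net_bending_force_vanishes(self, unit_icosphere_n2):
        f = bending_force(unit_icosphere_n2, 1.0)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_per_vertex_positive(self, jittered_mesh):
        assert np.all(helfrich_vertex(jittered_mesh, 1.0) >= 0)


# ------------------------------------------------------ penalties and tension


class TestPenalties:
    def test_volume_energy_values(self, membrane_sphere):
        V = enclosed_volume(membrane_sphere)
        assert volume_energy(membrane_sphere, 4.0, V) == 0.0
        # V at 60% of target: E_v = k_v (0.4 V0)^2 / V0 = 0.16 k_v V0
        V0 = V / 0.6
        assert np.isclose(volume_energy(membrane_sphere, 4.0, V0), 0.16 * 4.0 * V0)

    def test_quadratic_symmetry(self, membrane_sphere):
        V = enclosed_volume(membrane_sphere)
        assert np.isclose(volume_energy(membrane_sphere, 4.0, V + 5.0),
                          volume_energy(membrane_sphere, 4.0, V - 5.0), rtol=0.3)

    def test_volume_area_gradients(self, jittered_mesh):
        Gfd = fd_gradient(tc.enclosed_volume, jittered_mesh)
        assert np.abs(volume_gradient(jittered_mesh) - Gfd).max() < 1e-6
        Gfd = fd_gradient(tc.surface_area, jittered_mesh)
        assert np.abs(area_gradient(jittered_mesh) - Gfd).max() < 1e-6

    def test_area_energy_zero_at_target(self, membrane_sphere):
        assert area_energy(membrane_sphere, 8.0, surface_area(membrane_sphere)) == 0.0


class TestLocalTension:
    def test_zero_at_reference(self, membrane_sphere):
        s0 = tc.mixed_voronoi_area(membrane_sphere)
        assert local_tension_energy(membrane_sphere, 12.0, s0, 1.0) == 0.0

    def test_reservoir_scaling_raises_energy(self, membrane_sphere):
        s0 = tc.mixed_voronoi_area(membrane_sphere)
        assert local_tension_energy(membrane_sphere, 12.0, 1.33 * s0, 1.0) > 0.0

    def test_single_vertex_perturbation_formula(self, membrane_sphere):
        m = membrane_sphere.copy()
        s0 = tc.mixed_voronoi_area(m)
        m.density[5] = 2.0
        av = tc.mixed_voronoi_area(m)
        expected = sum(12.0 * (av[i] / m.density[i] - s0[i]) ** 2 / s0[i]
                       for i in range(m.n_vertices))
        assert np.isclose(local_tension_energy(m, 12.0, s0, 1.0), expected)

    def test_gradient_matches_finite_difference(self, jittered_mesh, rng):
        s0 = tc.mixed_voronoi_area(jittered_mesh)
        jittered_mesh.density = 1.0 + 0.1 * rng.random(jittered_mesh.n_vertices)
        G = local_tension_gradient(jittered_mesh, 12.0, s0, 1.0)
        Gfd = fd_gradient(lambda ms: local_tension_energy(ms, 12.0, s0, 1.0),
                          jittered_mesh)
        assert np.abs(G - Gfd).max() < 1e-4 * np.abs(Gfd).max()


# ----------------------------------------------------------- control points


class TestControlPoints:
    def test_zero_force_at_rest(self, membrane_sphere):
        v = 3
        cps = ControlPointSet(membrane_sphere.positions[v].copy(), [v], k_ex=20.0)
        # every coupled vertex except the target itself is displaced, so only
        # check the target contribution with all couplings at their anchors
        f = external_spring_force(membrane_sphere, cps)
        ring = membrane_sphere.one_ring(v)
        # target sits at the control point: zero force there
        assert np.allclose(f[v], 0.0)
        assert len(ring) > 0

    def test_force_linear_in_displacement(self, membrane_sphere):
        v = 3
        point = membrane_sphere.positions[v] + np.array([0.5, 0, 0])
        cps = ControlPointSet(point, [v], k_ex=20.0)
        f1 = external_spring_force(membrane_sphere, cps)[v]
        cps2 = ControlPointSet(membrane_sphere.positions[v] + np.array([1.0, 0, 0]),
                               [v], k_ex=20.0)
        f2 = external_spring_force(membrane_sphere, cps2)[v]
        assert np.allclose(2.0 * f1, f2)

    def test_energy_consistency(self, membrane_sphere, rng):
        m = membrane_sphere.copy()
        cps = ControlPointSet(m.positions[7] + rng.standard_normal(3), [7], k_ex=5.0)
        f = external_spring_force(m, cps)
        Gfd = fd_gradient(lambda ms: external_spring_energy(ms, cps), m)
        assert np.abs(f + Gfd).max() < 1e-5

    def test_active_window(self, membrane_sphere):
        cps = ControlPointSet(membrane_sphere.positions[2] + 1.0, [2], k_ex=1.0,
                              active=[(10, 20)])
        assert np.allclose(external_spring_force(membrane_sphere, cps, step=5), 0.0)
        assert not np.allclose(external_spring_force(membrane_sphere, cps, step=15), 0.0)


def test_total_force_is_sum_of_components(membrane_sphere, rng):
    cfg = SimulationConfig(V0_target=enclosed_volume(membrane_sphere),
                           S0_target=surface_area(membrane_sphere))
    noise = rng.standard_normal(membrane_sphere.positions.shape)
    from memremesh.energetics import constraint_gradient, ring_average
    f = total_force(membrane_sphere, cfg, None, noise=noise)
    expected = (internal_force(membrane_sphere, cfg.potential)
                + bending_force(membrane_sphere, cfg.kappa, cfg.C0)
                - ring_average(membrane_sphere, constraint_gradient(membrane_sphere, cfg))
                + noise)
    assert np.abs(f - expected).max() < 1e-12
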