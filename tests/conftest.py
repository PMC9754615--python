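import numpy as np
import pytest

from memremesh.energetics import PotentialParams
from memremesh.io_cli import SimulationConfig, icosphere_with_edge, optimal_sphere
from memremesh.trimesh_core import build_fused_spheres, build_icosphere


@pytest.fixture(scope="session")
def table_params() -> PotentialParams:
    return PotentialParams()


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def unit_icosphere_n2():
    return build_icosphere(2, radius=1.0)


@pytest.fixture(scope="session")
def unit_icosphere_n4():
    return build_icosphere(4, radius=1.0)


@pytest.fixture(scope="session")
def membrane_sphere():
    """Icosphere scaled so the mean edge length equals l0 = 1."""
    return icosphere_with_edge(2, 1.0)


@pytest.fixture(scope="session")
def fused_pair():
    return build_fused_spheres(2, radius=3.8)


@pytest.fixture(scope="session")
def tuned_sphere():
    """Sphere mesh optimized for per-vertex bending accuracy (n = 3)."""
    return optimal_sphere(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def jittered_mesh(rng):
    """Small irregular closed mesh for gradient oracles (has obtuse faces)."""
    m = build_icosphere(1, radius=2.0)
    m.positions = m.positions + 0.05 * rng.standard_normal(m.positions.shape)
    return m


def fd_gradient(fun, mesh, h=1e-6):
    """Central finite difference of a scalar mesh functional (the universal
    gradient oracle used across the energy tests)."""
    G = np.zeros_like(mesh.positions)
    for i in range(mesh.n_vertices):
        for a in range(3):
            orig = mesh.positions[i, a]
            mesh.positions[i, a] = orig + h
            ep = fun(mesh)
            mesh.positions[i, a] = orig - h
            em = fun(mesh)
            mesh.positions[i, a] = orig
            G[i, a] = (ep - em) / (2.0 * h)
    return G
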