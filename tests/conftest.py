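import numpy as np
import pytest

from memdot.mesh import CorticalMesh, build_phantom_mesh, synth_sensitivity, field_of_view
from memdot.montage import build_double_density, project_to_sphere
from memdot.pipeline import RunConfig, build_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default-configuration phantom: mesh, montage, sensitivity."""
    cfg = RunConfig()
    mesh, montage, sens = build_phantom(cfg)
    return cfg, mesh, montage, sens


@pytest.fixture(scope="session")
def small_mesh():
    return build_phantom_mesh(400, 4, random_seed=3)


@pytest.fixture(scope="session")
def dd_montage():
    return build_double_density()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_chain_mesh(n: int, edge_mm: float = 2.0) -> CorticalMesh:
    """A degenerate strip mesh whose shortest paths follow a chain.

    Vertices sit on a line at ``edge_mm`` spacing; consecutive triangles
    (i, i+1, i+2) create chain edges of length ``edge_mm`` and skip edges of
    ``2 * edge_mm``, so the chain is always the shortest route.
    """
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * edge_mm
    tris = np.array([[i, i + 1, i + 2] for i in range(n - 2)])
    return CorticalMesh(vertex_positions=pos, triangles=tris, scalp_radius=1e6)
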