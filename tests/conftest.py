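import numpy as np
import pytest
import trimesh

from liverreg import (
    PhantomSpec,
    TetVolumeMesh,
    TriSurfaceMesh,
    generate_phantom,
)


@pytest.fixture(scope="session")
def phantom():
    """Default-spec synthetic organ (the study conditions)."""
    return generate_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse organ for fast deformable-registration unit tests."""
    return generate_phantom(PhantomSpec(subdivisions=2, n_targets=40, seed=3))


@pytest.fixture(scope="session")
def sphere_mesh():
    """Unit-sphere triangulation for analytic coverage checks."""
    ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return TriSurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def cube_tet_mesh():
    """Structured tet mesh of the unit cube (5 tets per voxel cell)."""
    n = 4
    xs = np.linspace(0.0, 1.0, n + 1)
    grid = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1)
    nodes = grid.reshape(-1, 3)

    def nid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    tets = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                v = [
                    nid(i, j, k), nid(i + 1, j, k), nid(i, j + 1, k),
                    nid(i + 1, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i, j + 1, k + 1), nid(i + 1, j + 1, k + 1),
                ]
                # 5-tet decomposition, parity-alternated for conformity
                if (i + j + k) % 2 == 0:
                    cells = [
                        (0, 1, 3, 5), (0, 3, 2, 6), (0, 5, 6, 4),
                        (3, 5, 6, 7), (0, 3, 6, 5),
                    ]
                else:
                    cells = [
                        (1, 0, 2, 4), (1, 2, 3, 7), (1, 4, 5, 7),
                        (2, 4, 6, 7), (1, 2, 7, 4),
                    ]
                tets.extend([tuple(v[c] for c in cell) for cell in cells])
    return TetVolumeMesh(nodes, np.asarray(tets))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
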