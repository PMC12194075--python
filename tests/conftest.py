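import numpy as np
import pytest

from blastosim.mesh import CellMesh, TriMesh, build_icosphere


@pytest.fixture(scope="session")
def ico2():
    """Level-2 icosphere (162 vertices), the fast-test cell size."""
    return build_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    """Level-3 icosphere (642 vertices), the full-size cell."""
    return build_icosphere(3)


def make_cube_mesh() -> TriMesh:
    """Unit cube triangulated into 12 outward-wound faces."""
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    # index: (x, y, z) bits -> 4x + 2y + z
    faces = np.array([
        # z = 0 (normal -z)
        [0, 2, 6], [0, 6, 4],
        # z = 1 (normal +z)
        [1, 5, 7], [1, 7, 3],
        # y = 0 (normal -y)
        [0, 4, 5], [0, 5, 1],
        # y = 1 (normal +y)
        [2, 3, 7], [2, 7, 6],
        # x = 0 (normal -x)
        [0, 1, 3], [0, 3, 2],
        # x = 1 (normal +x)
        [4, 6, 7], [4, 7, 5],
    ])
    edges = np.unique(
        np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
            axis=1,
        ),
        axis=0,
    )
    return TriMesh(positions=v, edges=edges, faces=faces)


@pytest.fixture(scope="session")
def cube():
    return make_cube_mesh()
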