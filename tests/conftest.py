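import numpy as np
import pytest

from rttms.mesh_core import HeadMesh, make_layered_sphere_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Small 5-shell sphere phantom (fast; ~4k tets)."""
    return make_layered_sphere_phantom(radii=(20.0, 25.0, 28.0, 32.0, 35.0),
                                       target_edge=8.0)


@pytest.fixture(scope="session")
def small_mesh(small_phantom):
    return small_phantom[0]


@pytest.fixture(scope="session")
def homog_sphere():
    """Homogeneous conducting ball, radius 30 mm."""
    mesh, scalp, _ = make_layered_sphere_phantom(radii=(30.0,), target_edge=8.0,
                                                 conductivities=(0.275,))
    return mesh, scalp


def single_tet_mesh(sigma=1.0, label=2, scale=1.0):
    """One positively oriented tetrahedron."""
    nodes = scale * np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    return HeadMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([label]),
                    np.array([sigma]), roi_mask=np.array([True]))


def regular_tet_mesh(edge=1.0, sigma=0.275, label=2):
    """Regular tetrahedron with the given edge length."""
    nodes = edge * np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0],
        [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]])
    return HeadMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([label]),
                    np.array([sigma]), roi_mask=np.array([True]))
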