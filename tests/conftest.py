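import numpy as np
import pytest

from fibrestore import CohortParams, TriMesh, generate_bone_pair

# coarser mesh for tests that only need plumbing, not precision
COARSE = dict(ring_spacing_mm=6.0, n_theta=24)


@pytest.fixture(scope="session")
def zero_noise_params():
    return CohortParams(scale_sigma=0.0, shape_noise_mm=0.0, length_jitter_mm=0.0)


@pytest.fixture(scope="session")
def zero_noise_pair(zero_noise_params):
    return generate_bone_pair(zero_noise_params, seed=1)


@pytest.fixture(scope="session")
def default_pair():
    return generate_bone_pair(CohortParams(), seed=7)


@pytest.fixture
def tetrahedron():
    """Regular tetrahedron with positive signed volume."""
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriMesh(v, f)


def make_cube(center=(0.0, 0.0, 0.0), side=1.0):
    """Axis-aligned cube (8 vertices, 12 triangles) with outward winding."""
    c = np.asarray(center, dtype=float)
    h = side / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-h, h) for sy in (-h, h) for sz in (-h, h)]
    ) + c
    # index = 4*ix + 2*iy + iz
    quads = [
        (0, 1, 3, 2),  # -x
        (4, 6, 7, 5),  # +x
        (0, 4, 5, 1),  # -y
        (2, 3, 7, 6),  # +y
        (0, 2, 6, 4),  # -z
        (1, 5, 7, 3),  # +z
    ]
    faces = []
    for a, b, cc, d in quads:
        faces.append((a, b, cc))
        faces.append((a, cc, d))
    return TriMesh(corners, np.array(faces))


@pytest.fixture
def cube():
    return make_cube()


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
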