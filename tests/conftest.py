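"""Shared fixtures: phantom cases, plans, and small analytic meshes.

Heavy objects (the subdivided phantom and its surgical plan) are built once
per session; tests must not mutate them.
"""

import numpy as np
import pytest

from recontour import PhantomSpec, build_plan, make_phantom
from recontour.geometry import Plane, TriMesh


@pytest.fixture(scope="session")
def phantom_case():
    """Default phantom: 6 mm lesion bump on the right, 5120 faces."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_plan(phantom_case):
    return build_plan(phantom_case.mesh, phantom_case.true_plane, "right")


@pytest.fixture(scope="session")
def symmetric_case():
    """Lesion-free phantom (height 0): exactly bilaterally symmetric."""
    return make_phantom(PhantomSpec(lesion_height_mm=0.0))


def make_planar_patch(size_mm: float = 10.0, n: int = 11, z: float = 0.0) -> TriMesh:
    """A size×size mm square grid in the z-plane, triangulated, normals +z."""
    xs, ys = np.meshgrid(np.linspace(0, size_mm, n), np.linspace(0, size_mm, n))
    vertices = np.c_[xs.ravel(), ys.ravel(), np.full(n * n, z)]
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b, c, d = a + 1, a + n, a + n + 1
            faces += [[a, b, d], [a, d, c]]
    return TriMesh(vertices, np.array(faces))


@pytest.fixture
def planar_patch():
    return make_planar_patch()


def random_rigid(rng: np.random.Generator, trans_scale: float = 50.0,
                 source: str = "a", target: str = "b"):
    """A uniformly random proper rigid transform (for property tests)."""
    from scipy.spatial.transform import Rotation

    from recontour import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.normal(0, trans_scale, 3), source, target)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
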