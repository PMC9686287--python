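import numpy as np
import pytest

from fcdmap import synth
from fcdmap.surface import SurfaceMesh


@pytest.fixture(scope="session")
def icosphere3() -> SurfaceMesh:
    """642-vertex icosphere, the standard analysis fixture."""
    return synth.generate_surface(3)


@pytest.fixture(scope="session")
def icosphere2() -> SurfaceMesh:
    return synth.generate_surface(2)


@pytest.fixture(scope="session")
def icosahedron() -> SurfaceMesh:
    return synth.generate_surface(0)


@pytest.fixture()
def triangle_mesh() -> SurfaceMesh:
    return SurfaceMesh(
        vertex_coords=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        triangles=np.array([[0, 1, 2]]),
    )


@pytest.fixture(scope="session")
def cohort144():
    return synth.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 40-subject cohort for fast group analyses."""
    return synth.generate_cohort(40, 20, 20, seed=11)
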