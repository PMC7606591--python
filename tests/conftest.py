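import numpy as np
import pytest

from surfmorph import Mesh, generate_cohort, make_icosphere


@pytest.fixture(scope="session")
def ico2():
    """Icosphere at subdivision 2 (162 vertices), calibration-scale radius."""
    return make_icosphere(2, radius=20.0)


@pytest.fixture(scope="session")
def ico3():
    """Icosphere at subdivision 3 (642 vertices), edge ~2.6 mm."""
    return make_icosphere(3, radius=20.0)


@pytest.fixture(scope="session")
def ico4():
    """Icosphere at subdivision 4 (2562 vertices) for recovery scenarios."""
    return make_icosphere(4, radius=40.0)


@pytest.fixture(scope="session")
def triangle_mesh():
    coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    faces = np.array([[0, 1, 2]])
    return Mesh(coords, faces)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(seed=1)
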