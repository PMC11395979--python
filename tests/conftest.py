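import pytest

import aortameta as am
from aortameta.cohort import default_branches, make_tube_mesh_straight
from aortameta.morphometry import extract_centerline


@pytest.fixture(scope="session")
def default_cohort():
    """One 60-record cohort at the default study conditions."""
    return am.generate_cohort(am.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Zero-noise cohort: hemodynamics are exactly the balance model."""
    return am.generate_cohort(am.CohortConfig(seed=42).with_noise_scale(0.0))


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Straight cylinder, radius 5 mm, length 60 mm, fine ring."""
    return make_tube_mesh_straight(5.0, 60.0, n_circ=96, n_axial=80)


@pytest.fixture(scope="session")
def cylinder_centerline(cylinder_mesh):
    return extract_centerline(cylinder_mesh, [5.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def stenosed_aorta():
    """Synthetic aorta with a 40% mid-descending narrowing and branches."""
    a = am.coa_aorta(depth=0.4)
    a.branches.extend(default_branches(a))
    return a


@pytest.fixture(scope="session")
def stenosed_mesh(stenosed_aorta):
    return am.make_tube_mesh(stenosed_aorta, n_circ=48, n_axial=300)


@pytest.fixture(scope="session")
def stenosed_centerline(stenosed_mesh):
    return extract_centerline(stenosed_mesh, [0.0, 2.0, 0.0])
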