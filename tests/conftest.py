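import numpy as np
import pytest

from lvdose import phantom as ph
from lvdose.volumes import Grid


@pytest.fixture(scope="session")
def default_spec():
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def fine_grid():
    """1.0 mm isotropic grid; odd voxel count keeps voxel faces generic
    with respect to the canonical phantom's basal cut plane."""
    return Grid.centered(147, 1.0)


@pytest.fixture(scope="session")
def study_grid():
    return Grid.centered(64, 2.25)


@pytest.fixture(scope="session")
def default_phases(default_spec, fine_grid):
    """Voxelized ED/ES label+image pairs of the canonical phantom."""
    ed = ph.voxelize_phase(default_spec, "ED", fine_grid)
    es = ph.voxelize_phase(default_spec, "ES", fine_grid)
    return {"ED": ed, "ES": es}


@pytest.fixture(scope="session")
def coarse_phases(default_spec, study_grid):
    ed = ph.voxelize_phase(default_spec, "ED", study_grid)
    es = ph.voxelize_phase(default_spec, "ES", study_grid)
    return {"ED": ed, "ES": es}


@pytest.fixture(scope="session")
def small_cohort():
    return ph.generate_cohort(3, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
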