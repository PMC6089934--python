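import numpy as np
import pytest

from sparsebone.evaluation import StudyConfig, run_study
from sparsebone.phantoms import PhantomSpec, make_plate_phantom, make_rod_phantom


@pytest.fixture(scope="session")
def default_study():
    """The desk-scale study at its default conditions (6 + 6 samples,
    (64, 32, 32) lattice, 260-view short scan, master seed 0).

    Session-scoped: it is the expensive end-to-end run shared by the
    evaluation-level checks.
    """
    return run_study(StudyConfig(master_seed=0))


@pytest.fixture()
def plate_phantom():
    """225 um slabs spaced 300 um on a 25 um grid: Tb.Th/Tb.S oracle."""
    spec = PhantomSpec(grid_shape=(40, 32, 32))
    return make_plate_phantom(225.0, 300.0, spec)


@pytest.fixture()
def rod_phantom():
    """100 um radius rods at 500 um pitch along z: EF sign oracle."""
    spec = PhantomSpec(grid_shape=(40, 40, 40))
    return make_rod_phantom(100.0, 500.0, 0, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
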