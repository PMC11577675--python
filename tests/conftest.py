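import time

import pytest

from osteokin.anatomy import CohortSpec, generate_cohort
from osteokin.osteotomy import run_osteotomy_grid
from osteokin.squat import run_experiment


@pytest.fixture(scope="session")
def small_cohort():
    """Two limbs with meshes, for mesh-level tests."""
    return generate_cohort(CohortSpec(n_limbs=2, seed=3))


@pytest.fixture(scope="session")
def default_cohort():
    """The default 13-limb cohort, landmarks only (meshes not needed)."""
    return generate_cohort(CohortSpec(n_limbs=13, seed=0), with_meshes=False)


@pytest.fixture(scope="session")
def default_grid(default_cohort):
    """Full default osteotomy grid (2 variants x 7 heights), landmark level."""
    return run_osteotomy_grid(default_cohort, with_meshes=False)


@pytest.fixture(scope="session")
def full_experiment(default_cohort, default_grid):
    """Full default squat experiment; also records its wall-clock runtime."""
    t0 = time.time()
    result = run_experiment(default_cohort, default_grid)
    return result, time.time() - t0
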