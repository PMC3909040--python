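import numpy as np
import pytest

from midbrainfc import (
    BoldRun,
    CohortDesign,
    EffectSpec,
    balanced_cohort_design,
    make_phantom_geometry,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def geometry():
    return make_phantom_geometry()


@pytest.fixture(scope="session")
def small_design():
    """Four subjects (2 low span, 2 high span), two sessions each."""
    return balanced_cohort_design(n_low=2, n_high=2, rng_seed=11)


@pytest.fixture(scope="session")
def small_cohort(geometry, small_design):
    effect = EffectSpec()
    runs, truth = simulate_cohort(geometry, small_design, effect,
                                  n_timepoints=120, rng_seed=11)
    return runs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_run(data, tr=2.0, voxel=(2.0, 2.0, 2.0), **labels):
    affine = np.diag([*voxel, 1.0])
    return BoldRun(data=np.asarray(data, dtype=float), tr=tr, affine=affine, **labels)
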