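import numpy as np
import pytest

import cerebsig as cs


def small_config(**overrides) -> cs.SimulationConfig:
    """A fast default: 14^3 grid, four small groups."""
    base = dict(
        grid_shape=(14, 14, 14),
        n_regions=9,
        group_sizes={"HC": 6, "SCA2like": 6, "SCA3like": 6, "SCA7like": 6},
        seed=0,
    )
    base.update(overrides)
    return cs.SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_cohort() -> cs.SimulatedCohort:
    """One shared small cohort for read-only tests."""
    return cs.simulate(small_config())


@pytest.fixture(scope="session")
def default_adjustment(default_cohort):
    mask = cs.gm_mask(atlas=default_cohort.atlas)
    result = cs.run_adjustment(default_cohort.maps, default_cohort.table, mask)
    return mask, result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
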