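import numpy as np
import pytest

import morphancestry as ma


@pytest.fixture(scope="session")
def small_template():
    """3x3 grid dome, the smallest valid template."""
    return ma.make_template(9, extent=1.0)


@pytest.fixture(scope="session")
def grid_template():
    """10x10 grid dome used by most mid-size tests."""
    return ma.make_template(100, extent=100.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small default-structure cohort (10/region, 100 landmarks)."""
    cfg = ma.GeneratorConfig(n_per_region=10, n_landmarks=100, seed=7)
    return ma.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
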