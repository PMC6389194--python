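import numpy as np
import pytest

import crackletrace as ct
from crackletrace import pipeline


@pytest.fixture(scope="session")
def matrix():
    return ct.build_default_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lav_observations():
    """Fully re-analyzed default lavage-injury scenario.

    6 subjects x 4 PEEP levels, 20 s multi-channel recordings and HU frame
    series, run through the complete acoustic + volumetric pipeline.
    Session-scoped: this is the expensive end-to-end computation shared by
    the recovery tests.
    """
    cfg = ct.ScenarioConfig(seed=1, conditions=("LAV",))
    return pipeline.build_observation_table(cfg)


@pytest.fixture(scope="session")
def tiny_config():
    """One-cell scenario for fast structural tests."""
    return ct.ScenarioConfig(seed=7, n_subjects=1, conditions=("LAV",),
                             peep_levels=(0,))
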