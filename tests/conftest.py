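import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from csfpairs import preprocess
from csfpairs.pipeline import preprocess_cohort
from csfpairs.synthgen import CohortConfig, generate_cohort, \
    inject_technical_effects

settings.register_profile("ci", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("ci")


SMALL_KW = dict(n_neg=40, n_pos=30, n_peripheral=6, n_amyloid=5, n_tau=4,
                plates=2, positions_per_plate=40, missing_cog_frac=0.2,
                seed=7)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(**SMALL_KW)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A small injected discovery-like cohort shared across tests."""
    return inject_technical_effects(generate_cohort(small_config),
                                    duplicate_run=True)


@pytest.fixture(scope="session")
def small_prep(small_cohort):
    return preprocess_cohort(small_cohort, preprocess.QCThresholds())


def rng(seed=0):
    return np.random.default_rng(seed)
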