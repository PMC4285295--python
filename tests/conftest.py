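"""Shared fixtures.

The expensive simulated objects (a seven-model reference table and its
leave-one-out cross-validation) are session-scoped and shared across
the directional tests so the suite simulates them exactly once.
"""

import warnings

import numpy as np
import pytest

from triadmix.models import MODEL_IDS, ModelSpec, simulation_priors
from triadmix.simulate import SampleConfig, build_reference_table
from triadmix.sumstats import StatConfig
from triadmix.validation import leave_one_out_model_cv

# The moment statistics of rare site categories are legitimately
# constant in small tables; the rejection step warns when dropping them.
warnings.filterwarnings("ignore", message=".*constant statistic column.*")


@pytest.fixture(scope="session")
def sim_priors():
    return simulation_priors()


@pytest.fixture(scope="session")
def full_stat_config():
    return StatConfig("full_3pop")


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale sampling design: 200 loci x 500 bp, 1 diploid/pop."""
    return SampleConfig.diploid(1, 200, 500)


@pytest.fixture(scope="session")
def seven_model_table(sim_priors, desk_config, full_stat_config):
    """7 models x 400 prior draws at the desk-scale design."""
    models = [ModelSpec(m) for m in MODEL_IDS]
    return build_reference_table(
        models, sim_priors, desk_config, 400, full_stat_config, seed=11
    )


@pytest.fixture(scope="session")
def model_cv(seven_model_table):
    """Leave-one-out model-selection CV on the shared table."""
    return leave_one_out_model_cv(
        seven_model_table, replicates_per_model=25, tolerance=0.1, seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
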