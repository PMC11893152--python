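import numpy as np
import pytest

from factorialmr import GeneratorConfig, compute_score, generate_cohort, sim_config


@pytest.fixture(scope="session")
def default_cohort_50k():
    """One default-configuration cohort at the scale of the moment checks.

    Shared session-wide: several tests compare column moments and adjusted
    contrasts against the generating parameters on this single cohort.
    """
    config = GeneratorConfig.default(n_individuals=50_000, seed=104)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def sim_cohort_20k():
    """A two-arm scenario cohort with a known per-50 hazard-ratio truth."""
    config = sim_config(20_000, seed=7, hr50_a=0.85)
    return config, generate_cohort(config)


def scores_for(cohort, config, name):
    return compute_score(cohort.dosages(), config.scores[name].weight_table(name))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
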