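import numpy as np
import pytest

from predictprostate import load_default_model
from predictprostate.simulate import (
    CohortScenario,
    sample_covariates,
    simulate_outcomes,
)


@pytest.fixture(scope="session")
def default_model():
    return load_default_model()


@pytest.fixture(scope="session")
def cohort_factory(default_model):
    """Generate a synthetic cohort of size n for a seed (cached per call args)."""
    cache = {}

    def make(n=2000, seed=0, **scenario_kwargs):
        key = (n, seed, tuple(sorted(scenario_kwargs.items())))
        if key not in cache:
            scen = CohortScenario(n=n, seed=seed, **scenario_kwargs)
            rng = np.random.default_rng(seed)
            df = sample_covariates(scen, rng)
            cache[key] = simulate_outcomes(df, default_model, scen, rng)
        return cache[key].copy()

    return make


@pytest.fixture(scope="session")
def medium_cohort(cohort_factory):
    """One shared 4,000-subject cohort from the shipped model."""
    return cohort_factory(n=4000, seed=17)
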