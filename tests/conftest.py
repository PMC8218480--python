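import numpy as np
import pytest

import multistate_aging as ma


@pytest.fixture(scope="session")
def presets():
    return ma.truth_presets()


@pytest.fixture(scope="session")
def realistic(presets):
    return presets["realistic"]


@pytest.fixture(scope="session")
def truth_table(realistic):
    return realistic.rate_table()


@pytest.fixture(scope="session")
def fitted_models(realistic):
    """Point fit on a mid-sized synthetic survey (shared across tests)."""
    from multistate_aging.estimation import (
        COGNITIVE,
        FUNCTIONAL,
        build_transition_pairs,
        fit_transition_model,
    )

    survey = ma.generate_survey(
        realistic, ma.GeneratorConfig(n_respondents=5000, weight_dist="unit"), seed=11
    )
    rng = np.random.default_rng(11)
    cog = fit_transition_model(build_transition_pairs(survey, COGNITIVE, rng), COGNITIVE)
    fun = fit_transition_model(build_transition_pairs(survey, FUNCTIONAL, rng), FUNCTIONAL)
    return survey, cog, fun


@pytest.fixture(scope="session")
def projection(realistic, truth_table):
    demo = ma.generate_demographics(realistic.scenario, seed=0)
    result = ma.project(demo, truth_table)
    return result
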