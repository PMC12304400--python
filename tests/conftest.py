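import numpy as np
import pytest

from banditx import (
    CohortSpec,
    HorizonParams,
    RestlessParams,
    TwoArmedParams,
    generate_horizon_rewardset,
    generate_restless_rewardset,
    generate_synthetic_cohort,
    generate_twoarmed_rewardset,
    restless_learner_config,
    simulate_session,
    twoarmed_learner_config,
)


@pytest.fixture(scope="session")
def restless_rewardset():
    return generate_restless_rewardset(seed=0)


@pytest.fixture(scope="session")
def horizon_rewardset():
    return generate_horizon_rewardset(seed=0)


@pytest.fixture(scope="session")
def twoarmed_rewardset():
    return generate_twoarmed_rewardset(seed=0)


@pytest.fixture(scope="session")
def restless_cfg():
    return restless_learner_config()


@pytest.fixture(scope="session")
def twoarmed_cfg():
    return twoarmed_learner_config()


@pytest.fixture(scope="session")
def group_scale_params():
    """Group-scale parameter objects for each task's improved model."""
    return {
        "restless": RestlessParams(tau=0.15, beta=-0.41),
        "twoarmed": TwoArmedParams(beta0=0.0, w_value=0.13, w_directed=0.15),
        "horizon": HorizonParams(beta0_long=0.0, w_value_long=3.62, w_info_long=0.32),
    }


@pytest.fixture(scope="session")
def restless_session(restless_rewardset, restless_cfg, group_scale_params):
    return simulate_session(
        restless_rewardset, group_scale_params["restless"], restless_cfg, seed=7
    )


@pytest.fixture(scope="session")
def twoarmed_session(twoarmed_rewardset, twoarmed_cfg, group_scale_params):
    return simulate_session(
        twoarmed_rewardset, group_scale_params["twoarmed"], twoarmed_cfg, seed=7
    )


@pytest.fixture(scope="session")
def horizon_session(horizon_rewardset, group_scale_params):
    return simulate_session(horizon_rewardset, group_scale_params["horizon"], seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """30-subject two-session cohort at the default study conditions."""
    return generate_synthetic_cohort(CohortSpec(n_subjects=30, seed=0))
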