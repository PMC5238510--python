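import numpy as np
import pytest

from revlearn.models import ModelParams

# generative parameter vectors used throughout (drug / control estimates)
DRUG_PARAMS = ModelParams(eta=0.648, beta=2.12, alpha=0.41, omega=1.179)
CONTROL_PARAMS = ModelParams(eta=0.561, beta=2.18, alpha=0.44, omega=1.043)

#: reference cross-validation STDs for (eta, beta, alpha, omega)
DRUG_STDS = {"eta": 0.118, "beta": 0.048, "alpha": 0.126, "omega": 0.108}
CONTROL_STDS = {"eta": 0.081, "beta": 0.053, "alpha": 0.084, "omega": 0.092}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def drug_params():
    return DRUG_PARAMS


@pytest.fixture(scope="session")
def control_params():
    return CONTROL_PARAMS


@pytest.fixture(scope="session")
def small_trials():
    """Two short sessions of FW+Decay behaviour shared across tests."""
    from revlearn.task import simulate_block_set

    return simulate_block_set("FW+Decay", DRUG_PARAMS, n_blocks=10,
                              blocks_per_session=5, seed=7)
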