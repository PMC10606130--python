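import numpy as np
import pytest

from countssm.model import ArmaComponent, DrugComponent, StateSpaceModel
from countssm.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def default_sim():
    """One realization of the default simulated scenario."""
    return simulate_counts(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_model(default_sim):
    """The generating model of the default scenario."""
    return default_sim.config.true_model()


@pytest.fixture()
def small_model():
    """A compact one-drug-plus-ARMA model for fast fitting tests."""
    return StateSpaceModel(
        components=[
            DrugComponent(ar_coeff=0.6, control_gain=-0.4, control_index=0),
            ArmaComponent(ar1_coeff=0.5, ar2_coeff=0.1, ma_coeff=0.2, noise_sd=0.3),
        ],
        obs_noise_var=0.25,
        obs_kind="adh",
        control_dim=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
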