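import numpy as np
import pytest

from seedtrain.kinetic_model import CultureState, KineticParameters
from seedtrain.seed_train import PassagingRule, default_scales
from seedtrain.synthetic_data import (
    VariabilityConfig,
    generate_seed_train,
    nominal_initial_state,
    nominal_parameters,
)


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def init_state():
    return nominal_initial_state()


@pytest.fixture(scope="session")
def scales():
    return default_scales()


@pytest.fixture(scope="session")
def rule():
    return PassagingRule()


@pytest.fixture(scope="session")
def noiseless_record(nominal, scales, rule):
    """Noise-free seed train generated with the nominal parameters."""
    var = VariabilityConfig(
        measurement_cv=0.0, batch_mu_max_cv=0.0, scale1_mu_max_factor=1.0
    )
    rec, truth = generate_seed_train(
        [nominal] * 3, scales, rule, var, np.random.default_rng(0), seed_train_id="NOISELESS"
    )
    return rec, truth


@pytest.fixture
def saturated_params(nominal):
    """No death, no lysis, no decomposition, negligible uptake: the viable
    population grows exponentially at mu_max while substrates stay put."""
    return nominal.with_values(
        mu_d_max=0.0,
        mu_d_min=0.0,
        k_lys=0.0,
        k_Gln_decomp=0.0,
        q_Glc_max=0.0,
        q_Gln_max=0.0,
        K_Glc=1e-8,
        K_Gln=1e-8,
    )
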