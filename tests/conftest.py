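import numpy as np
import pytest

from plaidpercept import (
    PopulationConfig,
    StimulusKind,
    TrainingConfig,
    sample_population,
    train_readout,
    training_responses,
)


@pytest.fixture(scope="session")
def fig4_cells():
    """24 equispaced component cells, k=7, peak 1, background 0.1."""
    cfg = PopulationConfig(
        n_cells=24,
        fraction_component=1.0,
        pref_direction_scheme="equispaced",
        k=7.0,
        amplitude=1.0,
        baseline=0.1,
        trial_noise_sd=0.25,
        seed=0,
    )
    return sample_population(cfg)


@pytest.fixture(scope="session")
def fig4_model(fig4_cells):
    """Decision neuron trained on 0-vs-180 deg plaids over the component cells."""
    train = training_responses(fig4_cells, StimulusKind.PLAID, 200, 0.25, seed=11)
    return train_readout(train, TrainingConfig(StimulusKind.PLAID, 200, l2_lambda=1.0))


@pytest.fixture(scope="session")
def mixed_cells_small():
    """Reduced mixed population (200 cells, 80/20) with cross-orientation suppression."""
    cfg = PopulationConfig(
        n_cells=200,
        fraction_component=0.8,
        pref_direction_scheme="uniform_random",
        amplitude_distribution=(8.0, 1.0),
        baseline=2.0,
        trial_noise_sd=2.0,
        osi_target=(0.7, 0.1),
        dsi_target=(0.6, 0.2),
        component_plaid_suppression=0.5,
        pattern_plaid_k_divisor=4.0,
        seed=7,
    )
    return sample_population(cfg)


@pytest.fixture(scope="session")
def mixed_model_small(mixed_cells_small):
    train = training_responses(mixed_cells_small, StimulusKind.PLAID, 100, 2.0, seed=13)
    return train_readout(train, TrainingConfig(StimulusKind.PLAID, 100, l2_lambda=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
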