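"""Shared fixtures.

Heavier artifacts (trained auto-encoders, fixture acquisitions) are
session-scoped so each is built once per run.  The compact models train on
shortened echo trains (T=32) which keeps the suite fast while exercising
the same code paths as the full-length configurations.
"""

import numpy as np
import pytest

from latentmr.autoencoder import AutoEncoderSpec, TrainingConfig, train_autoencoder
from latentmr.dictionary import build_dictionary, testing_grid, training_grid
from latentmr.operators import make_shuffling_mask
from latentmr.phantom import default_fse_phantom_spec, make_coil_maps, make_phantom, simulate_acquisition

T_SHORT = 32


@pytest.fixture(scope="session")
def fse_dict_short():
    """Normalized T=32 FSE training dictionary."""
    return build_dictionary(training_grid("fse"), "fse", echo_count=T_SHORT)


@pytest.fixture(scope="session")
def fse_dict_short_raw():
    return build_dictionary(training_grid("fse"), "fse", echo_count=T_SHORT,
                            normalized=False)


@pytest.fixture(scope="session")
def fse_dict_short_test():
    return build_dictionary(testing_grid("fse"), "fse", echo_count=T_SHORT)


@pytest.fixture(scope="session")
def fse_ae_short(fse_dict_short):
    """L=1 tanh auto-encoder on the T=32 dictionary (reduced epochs)."""
    return train_autoencoder(fse_dict_short, AutoEncoderSpec(T_SHORT, 1),
                             TrainingConfig(epochs=30_000, seed=1))


@pytest.fixture(scope="session")
def fixture_truth():
    return make_phantom(default_fse_phantom_spec(echo_count=T_SHORT), seed=0)


@pytest.fixture(scope="session")
def fixture_acq(fixture_truth):
    coils = make_coil_maps(8, fixture_truth.series.shape[:2], seed=0)
    mask = make_shuffling_mask(8, T_SHORT, fixture_truth.series.shape[1], seed=0)
    return simulate_acquisition(fixture_truth, coils, mask, noise_sigma=1e-3,
                                seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
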