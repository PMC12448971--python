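"""Shared fixtures: small synthetic study datasets built at test time."""

from __future__ import annotations

import warnings

import pytest

from repspace import synthetic_data as sd

#: Fully shared subjective spaces (no participant idiosyncrasy).
SHARED_FULL = {"perceptual": 1.0, "conceptual": 1.0}


@pytest.fixture(scope="session")
def small_config():
    """12 concepts x 2 images: enough structure for every pipeline stage."""
    return sd.generate_latent_configuration(12, 2, seed=11)


@pytest.fixture(scope="session")
def noiseless_encoding(small_config):
    """Noiseless, fully shared ratings: exactly clipped coordinate differences."""
    return sd.simulate_encoding(small_config, n_participants=3,
                                trials_per_participant=80, noise_sd=0.0,
                                seed=21, shared_weight=SHARED_FULL)


@pytest.fixture(scope="session")
def noisy_encoding(small_config):
    return sd.simulate_encoding(small_config, n_participants=6,
                                trials_per_participant=120, noise_sd=8.0,
                                seed=22)


@pytest.fixture(scope="session")
def recognition(small_config, noisy_encoding):
    return sd.simulate_recognition(small_config, noisy_encoding,
                                   sd.DEFAULT_EFFECTS, seed=23)


@pytest.fixture(scope="session")
def feature_banks(small_config):
    return sd.simulate_feature_bank(small_config, sd.default_layer_specs(),
                                    seed=24)


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
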