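"""Shared fixtures: small synthetic trial sets generated at test time."""

import numpy as np
import pytest

from myokin import SynthConfig, generate_latent_mode, generate_raw_mode


@pytest.fixture(scope="session")
def latent_small():
    """Small latent-mode trial set with light noise."""
    cfg = SynthConfig(
        seed=7,
        D_true=4,
        n_instructions=5,
        n_repetitions=3,
        frames_per_trial=60,
        measurement_noise=0.2,
        marker_noise_mm=0.3,
    )
    return generate_latent_mode(cfg)


@pytest.fixture(scope="session")
def latent_noiseless():
    """Noise-free latent-mode trial set (exact low-rank structure)."""
    cfg = SynthConfig(
        seed=11,
        D_true=4,
        n_instructions=5,
        n_repetitions=3,
        frames_per_trial=60,
        measurement_noise=0.0,
        marker_noise_mm=0.0,
    )
    return generate_latent_mode(cfg)


@pytest.fixture(scope="session")
def raw_small():
    """Small raw-signal trial set (sEMG at 2048 Hz + markers at 100 Hz)."""
    cfg = SynthConfig(
        seed=5,
        D_true=4,
        n_instructions=4,
        n_repetitions=2,
        frames_per_trial=120,
    )
    return generate_raw_mode(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
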