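import numpy as np
import pytest

from folde import (SyntheticOracleConfig, TrainConfig, generate_landscape,
                   make_oracle)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale oracle config used across the suite."""
    return SyntheticOracleConfig(L=20, dim=24, naturalness_rho=0.5,
                                 signal_fraction=0.5, noise_sd=0.1, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    landscape, table = generate_landscape(small_config)
    return landscape


@pytest.fixture(scope="session")
def small_oracle(small_config):
    landscape, oracle = make_oracle(small_config)
    return landscape, oracle


@pytest.fixture(scope="session")
def small_train_config(small_config):
    return TrainConfig(input_dim=small_config.dim)


def random_psd(rng: np.random.Generator, n: int, jitter: float = 1e-3) -> np.ndarray:
    """Random symmetric positive-definite matrix."""
    A = rng.normal(size=(n, n))
    return A @ A.T / n + jitter * np.eye(n)
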