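import numpy as np
import pytest

from intvae import NetworkConfig, RegularizerSpec, SyntheticSpec, generate_multiomic


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny three-modality dataset for contract tests (n=120)."""
    spec = SyntheticSpec(n_samples=120, d_continuous=30, d_categorical=30,
                         d_clinical=20, latent_rank=4, seed=11)
    ds, gt = generate_multiomic(spec)
    return ds, gt


@pytest.fixture(scope="session")
def medium_dataset():
    """Mid-size dataset shared by training-behaviour tests (n=200)."""
    spec = SyntheticSpec(n_samples=200, d_continuous=50, d_categorical=50,
                         d_clinical=30, latent_rank=4, seed=5)
    ds, gt = generate_multiomic(spec)
    return ds, gt


def quick_config(architecture: str, **kw) -> NetworkConfig:
    """A small configuration for fast training in tests."""
    defaults = dict(architecture=architecture, latent_size=16, dense_size=64,
                    regularizer=RegularizerSpec("MMD", 50.0), epochs=3,
                    batch_size=64, seed=123)
    defaults.update(kw)
    return NetworkConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
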