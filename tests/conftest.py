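import numpy as np
import pytest

from refnoise import DatasetProfile, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small cohort with clear signal: 80 samples, 12 features, 4 informative."""
    profile = DatasetProfile(
        name="small", n_samples=80, n_features=12, prevalence=0.5,
        n_informative=4, effect_size=1.5, block_size=4, block_rho=0.6,
    )
    return generate(profile, seed=101)


@pytest.fixture(scope="session")
def null_dataset():
    """A label-independent cohort (effect size 0, uncorrelated features)."""
    profile = DatasetProfile(
        name="null", n_samples=100, n_features=30, prevalence=0.5,
        n_informative=0, effect_size=0.0, block_rho=0.0,
    )
    return generate(profile, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
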