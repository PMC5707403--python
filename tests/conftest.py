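import numpy as np
import pytest

from arrestomix.simulate import default_cohort_config, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One shared default synthetic cohort (seed 11)."""
    config = default_cohort_config(seed=11)
    quant, metadata, truth = generate_cohort(config)
    return config, quant, metadata, truth


def make_signal_dataset(rng, n=28, p=12, n_informative=1, effect=3.0, noise=0.5):
    """X with ``n_informative`` columns carrying a shared latent signal and
    the rest pure noise; y is the latent signal plus noise. Returns
    centered X and y."""
    latent = rng.normal(size=n)
    X = rng.normal(size=(n, p))
    X[:, :n_informative] += effect * latent[:, None]
    y = latent + noise * rng.normal(size=n)
    return X - X.mean(axis=0), y - y.mean()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
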