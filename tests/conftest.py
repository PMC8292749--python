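import numpy as np
import pytest

from thermacclim.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-fish cohort with default (study-condition) parameters."""
    cfg = SyntheticConfig(n_individuals=40, seed=5)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def noise_free_config():
    """Six fish, every stochastic term switched off: traces are exact lines."""
    return SyntheticConfig(
        n_individuals=6,
        seed=11,
        noise_sd_o2=0.0,
        activity_sigma=0.0,
        fraction_noisy_periods=0.0,
        cardiac_noise_sd_o2=0.0,
    )
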