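import numpy as np
import pytest

from fetalclock.model import GestationalClockModel, TrainConfig
from fetalclock.simulate import SimulationConfig, simulate_cohort_with_latents

# Reduced-scale training configs used throughout the unit tests: the window
# span (series_length / scans_per_day) is kept close to the full-scale
# setting so flank behaviour is representative while fits stay fast.
SMALL_TRAIN = TrainConfig(series_length=128, scans_per_day=6.0, seed=0)
MEDIUM_TRAIN = TrainConfig(series_length=256, scans_per_day=8.0, seed=0)


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(n_fetuses=400, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    cohort, _ = simulate_cohort_with_latents(small_sim_config)
    return cohort


@pytest.fixture(scope="session")
def small_results(small_cohort):
    return GestationalClockModel(small_cohort, SMALL_TRAIN).fit()


@pytest.fixture(scope="session")
def medium_cohort_and_latents():
    return simulate_cohort_with_latents(SimulationConfig(n_fetuses=1000, seed=1))


@pytest.fixture(scope="session")
def medium_cohort(medium_cohort_and_latents):
    return medium_cohort_and_latents[0]


@pytest.fixture(scope="session")
def medium_latents(medium_cohort_and_latents):
    return medium_cohort_and_latents[1]


@pytest.fixture(scope="session")
def medium_results(medium_cohort):
    return GestationalClockModel(medium_cohort, MEDIUM_TRAIN).fit()


@pytest.fixture(scope="session")
def medium_test_cohort():
    return simulate_cohort_with_latents(SimulationConfig(n_fetuses=300, seed=77))[0]


@pytest.fixture(scope="session")
def clean_sim_config():
    """No time-zero error, no growth heterogeneity, no measurement noise."""
    return SimulationConfig(
        n_fetuses=400, seed=3, sigma_tau_days=0.0, sigma_rho=0.0, cv_noise=0.0,
        monthly_peak_weight=0.0,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_sim_config):
    return simulate_cohort_with_latents(clean_sim_config)[0]


@pytest.fixture(scope="session")
def clean_results(clean_cohort):
    return GestationalClockModel(clean_cohort, SMALL_TRAIN).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
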