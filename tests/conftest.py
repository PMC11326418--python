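import numpy as np
import pytest

from infantflow import cohort


@pytest.fixture(scope="session")
def regional_cohort():
    """Default regional cohort (n=76, maps + ASL series), fixed seed."""
    return cohort.generate_cohort(cohort.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def regional_cohort_nomaps_ages():
    return np.sort(np.random.default_rng(0).uniform(1.4, 28.0, 76))


@pytest.fixture(scope="session")
def global_log_cohort():
    """Global-analysis cohort (n=119) from the logarithmic generator."""
    return cohort.generate_cohort(
        cohort.GeneratorConfig.global_cohort(trajectory_family="logarithmic",
                                             seed=21))


@pytest.fixture(scope="session")
def global_biphasic_cohort():
    return cohort.generate_cohort(
        cohort.GeneratorConfig.global_cohort(trajectory_family="biphasic",
                                             seed=22))
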