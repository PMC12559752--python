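import numpy as np
import pytest

from fbos.synthetic import (CohortConfig, StandingTrialConfig,
                            generate_cohort, generate_standing_trial)


@pytest.fixture(scope="session")
def noise_free_trial():
    """Standing trial with all noise sources off (40 s, both feet)."""
    cfg = StandingTrialConfig(duration=40.0, marker_noise_sd=0.0,
                              cop_tremor_sd=0.0, seed=7)
    return cfg, generate_standing_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """Standing trial at default noise levels."""
    cfg = StandingTrialConfig(duration=40.0, seed=11)
    return cfg, generate_standing_trial(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default (study-structure) configuration."""
    cfg = CohortConfig(seed=5)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
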