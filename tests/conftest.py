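import numpy as np
import pytest

from painpsych.synthetic import CohortConfig, generate_beta_maps, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-participant cohort with default study-design settings."""
    cfg = CohortConfig(n_participants=30, seed=42)
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def full_cohort():
    """A full-size (n=101) cohort for tests that need the study scale."""
    cfg = CohortConfig(seed=7)
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = CohortConfig(
        n_participants=12, seed=3, rating_noise_sd=0.0,
        between_subject_sd=0.0, modality_between_sd=0.0,
    )
    dataset, truth = generate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture()
def small_maps(small_cohort):
    """Coupled-regime beta maps on a small grid for the 30-participant cohort."""
    _, _, truth = small_cohort
    return generate_beta_maps(truth, "coupled", shape=(12, 12, 12), seed=5)
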