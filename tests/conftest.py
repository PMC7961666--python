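import numpy as np
import pytest

from iolstack import (
    SyntheticConfig,
    generate_cohort,
    optimize_all,
    split_patientwise,
)


@pytest.fixture(scope="session")
def small_cohort():
    """~200-eye cohort with the default (Haigis-truth) generative model."""
    return generate_cohort(SyntheticConfig(n_patients=120, seed=7))


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return split_patientwise(small_cohort, 30, seed=7)


@pytest.fixture(scope="session")
def small_constants(small_split):
    train, _ = small_split
    return optimize_all(train, per_model=False)


@pytest.fixture(scope="session")
def single_lens_cohort():
    """Single lens model, moderate noise; convenient for recovery checks."""
    cfg = SyntheticConfig(
        n_patients=400,
        seed=3,
        iol_models={"LENS-X": (1.0, 0.0)},
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero ELP and refraction noise: the optical closed loop is exact."""
    cfg = SyntheticConfig(
        n_patients=150,
        seed=11,
        elp_noise_sd=0.0,
        refraction_noise_sd=0.0,
        iol_models={"LENS-X": (1.0, 0.0)},
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_eyes(rng, n):
    """Biometry grids spanning the clinical range, as plain arrays."""
    return {
        "al": rng.uniform(21.0, 28.0, n),
        "r": rng.uniform(6.9, 8.6, n),
        "acd": rng.uniform(2.4, 3.9, n),
    }
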