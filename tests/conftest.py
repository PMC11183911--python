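import numpy as np
import pytest
from hypothesis import settings

from woundhurdle.hurdle_ancova import FitConfig
from woundhurdle.synthetic_cohort import (
    DEFAULT_TARGETS,
    calibrate_to_targets,
    default_params,
    generate_cohort,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def calibrated_params():
    """Generative parameters calibrated to the default population targets."""
    return calibrate_to_targets(DEFAULT_TARGETS, default_params(), seed=0)


@pytest.fixture(scope="session")
def small_cohort(calibrated_params):
    """A 41-subject cohort (23 arm-1, 18 arm-0), the reference cohort size."""
    return generate_cohort(calibrated_params, (23, 18), seed=7)


@pytest.fixture()
def quick_config():
    """A short sampler run for structural tests (not for inference checks)."""
    return FitConfig(n_chains=2, n_draws_per_chain=100, n_warmup=100, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240617)
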