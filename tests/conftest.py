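import pytest
from hypothesis import HealthCheck, settings

from circphase.params import ModelParameters
from circphase.synthetic import CohortSpec, generate_cohort

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Five noisy subjects with noiseless urine, for pipeline tests."""
    root = tmp_path_factory.mktemp("cohort_small")
    table = generate_cohort(
        root, CohortSpec(n_subjects=5, urine_noise_sd=0.0), seed=11)
    return root, table
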