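import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sample():
    """One deterministic synthetic dataset shared across tests."""
    from pvror.synthetic import SyntheticConfig, sample

    return sample(SyntheticConfig(n_cases=3000, target_share=0.3, seed=42))


@pytest.fixture(scope="session")
def small_cohort(small_sample):
    from pvror.cohort import build_cohort
    from pvror.dedup import deduplicate

    s = small_sample
    return build_cohort(deduplicate(s.demo), s.drug, s.reac, s.indi, s.outc)
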