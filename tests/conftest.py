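import hypothesis
import pytest

from slncalc.simulate import default_config, generate_cohort

hypothesis.settings.register_profile(
    "slncalc", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("slncalc")


@pytest.fixture(scope="session")
def study_config():
    """Study-shaped generator config (n=993, published marginals)."""
    return default_config(seed=1)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return generate_cohort(study_config)
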