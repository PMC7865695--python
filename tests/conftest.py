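import pandas as pd
import pytest
from hypothesis import settings

from mdsls import default_cohort_spec, generate_cohort
from mdsls.synth import analysis_parameters

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Study-condition synthetic cohort: 101 MDS / 88 healthy, d = 1.5."""
    return generate_cohort(default_cohort_spec(seed=42))


@pytest.fixture(scope="session")
def analysis_params(default_cohort) -> list[str]:
    return analysis_parameters(default_cohort)


@pytest.fixture(scope="session")
def planted_names() -> list[str]:
    from mdsls.synth import CRITICAL_PARAMETERS
    return sorted(CRITICAL_PARAMETERS)
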