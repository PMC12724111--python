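import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from trialcea.config import default_config
from trialcea.outcomes import add_qaly_columns
from trialcea.simulate import apply_missingness, generate_trial


def small_config(seed=0, **overrides):
    """A fast trial config (n=120, 6 sites) for unit tests."""
    base = dict(
        n_participants=120,
        allocation_ratio=(60, 60),
        n_sites=6,
    )
    base.update(overrides)
    return default_config(seed=seed, **base)


@pytest.fixture(scope="session")
def study_dataset():
    """One fully observed trial at the default study conditions."""
    return generate_trial(default_config(seed=314), include_service_use=False)


@pytest.fixture(scope="session")
def study_frame(study_dataset):
    return add_qaly_columns(study_dataset.participants)


@pytest.fixture(scope="session")
def masked_frame():
    """A masked (MAR) trial with QALY columns, as the analysis sees it."""
    ds = generate_trial(default_config(seed=159), include_service_use=False)
    return add_qaly_columns(apply_missingness(ds).participants)


@pytest.fixture(scope="session")
def small_frame():
    ds = generate_trial(small_config(seed=27), include_service_use=False)
    return add_qaly_columns(ds.participants)
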