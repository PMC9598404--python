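import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from opea.simulate import CohortSpec, write_fixtures

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Small self-consistent fixture set (cohort, traces, pairing, calibration, LMS)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    write_fixtures(outdir, spec=CohortSpec(n=40, seed=11))
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
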