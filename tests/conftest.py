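import pytest
from hypothesis import HealthCheck, settings

import chtii

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (1,064 samples, depth 200x)."""
    return chtii.simulate_cohort(chtii.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated cohort: VAFs ~0.12, carrier fraction ~0.08, depth 500x."""
    return chtii.simulate_cohort(chtii.well_separated_config(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, default_cohort):
    """Default cohort written out as a fixture bundle."""
    out = tmp_path_factory.mktemp("bundle")
    chtii.write_fixture_bundle(default_cohort, out)
    return out
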