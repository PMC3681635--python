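import pytest
from hypothesis import HealthCheck, settings

import starcut as sc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def taqii_canonical():
    """TaqII under stringent conditions: canonical GACCGA only, offsets (11, 9)."""
    return sc.taqii()


@pytest.fixture(scope="session")
def truth_enzyme():
    """Relaxed truth enzyme: canonical + 70 seeded constrained variants."""
    return sc.make_truth_enzyme(sc.TruthEnzymeSpec(seed=5))


@pytest.fixture(scope="session")
def single_substrate():
    return sc.make_pcr_substrate("single", seed=1)


@pytest.fixture(scope="session")
def wt_substrate():
    return sc.make_pcr_substrate("wt", seed=1)
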