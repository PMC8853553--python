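import pytest
from hypothesis import settings

import glomorph as g

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: documented default seed of the synthetic study protocol
SEED = 1

N_PROFILES = 600


@pytest.fixture(scope="session")
def cohorts():
    """Measurement tables for the full preset suite at the protocol scale."""
    return {name: g.simulate_cohort(g.get_preset(name), N_PROFILES, SEED)
            for name in g.list_presets()}


@pytest.fixture(scope="session")
def stereology_params():
    return g.StereologyParams()
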