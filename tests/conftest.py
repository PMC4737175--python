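import pytest

import nickplex as nx


@pytest.fixture(scope="session")
def panel():
    return nx.make_default_panel(context_seed=1)


@pytest.fixture(scope="session")
def model():
    return nx.MobilityModel()


@pytest.fixture(scope="session")
def quiet_spec():
    """Zero-noise trace parameters for exact-integration checks."""
    return nx.TraceSpec(noise_sd=0.0, seed=11)
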