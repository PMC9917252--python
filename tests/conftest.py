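import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def hpf_az():
    """One synthetic HPF-like AZ (fixed seed) shared across tests."""
    from aznano.synthgen import SyntheticParams, generate_az

    params = SyntheticParams.paper_hpf(seed=7)
    table, truth = generate_az(params)
    return table, truth, params


@pytest.fixture(scope="session")
def hpf_field():
    """One synthetic field (table, mask, truth) shared across tests."""
    from aznano.synthgen import SyntheticParams, generate_field

    params = SyntheticParams.paper_hpf(seed=11)
    return generate_field(params)
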