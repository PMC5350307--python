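import pytest

from reedcarbon import ModelParameters, SyntheticForcingSpec, generate_forcing, simulate


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def default_forcing():
    return generate_forcing(SyntheticForcingSpec())


@pytest.fixture(scope="session")
def default_trajectory(default_params, default_forcing):
    return simulate(default_params, default_forcing)
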