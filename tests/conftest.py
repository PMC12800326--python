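import logging

import pytest

from wcseizure import ModelParameters, SeizureModel, find_limit_cycle

logging.getLogger("wcseizure").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def baseline_params() -> ModelParameters:
    return ModelParameters.baseline()


@pytest.fixture(scope="session")
def baseline_model(baseline_params) -> SeizureModel:
    return SeizureModel(baseline_params)


@pytest.fixture(scope="session")
def baseline_cycle(baseline_model):
    cyc = find_limit_cycle(baseline_model)
    assert cyc is not None
    return cyc
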