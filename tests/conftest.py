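import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

import soilc13 as s


@pytest.fixture(scope="session")
def default_params():
    return s.KineticParams()


@pytest.fixture(scope="session")
def zero_noise_dataset(default_params):
    """Default design, seed 1, all measurement noise off; truth kept."""
    params = default_params.zero_noise()
    truth = s.simulate_design(params)
    tables = s.render_measurements(truth, params, seed=1)
    return {"params": params, "truth": truth, **tables}


@pytest.fixture(scope="session")
def pipeline_result(zero_noise_dataset):
    return s.run_pipeline(zero_noise_dataset["traps"], zero_noise_dataset["isotopes"])
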