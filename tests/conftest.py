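import numpy as np
import pytest

from sactmt_cea import CEModel, load_default


@pytest.fixture(scope="session")
def spec():
    return load_default()


@pytest.fixture(scope="session")
def model(spec):
    return CEModel(spec)


@pytest.fixture(scope="session")
def base_comparisons(model):
    return model.evaluate()


@pytest.fixture(scope="session")
def base_results(model):
    return model.strategy_results()


@pytest.fixture(scope="session")
def table1_curves():
    """The four base-case fitted curves (shape/scale convention)."""
    from sactmt_cea import ParametricSurvival

    return {
        ("sac_tmt", "pfs"): ParametricSurvival("lognormal", (2.20, 0.999)),
        ("sac_tmt", "os"): ParametricSurvival("loglogistic", (1.538, 27.354)),
        ("chemotherapy", "pfs"): ParametricSurvival("loglogistic", (2.420, 4.590)),
        ("chemotherapy", "os"): ParametricSurvival("weibull_ph", (1.599, 0.007)),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
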