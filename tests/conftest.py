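import pytest

from lungcea.screening import scenario_grid
from lungcea.synthetic import (GeneratorConfig, generate_parameter_set,
                               generate_population)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def gen_params(gen_config):
    params, truth = generate_parameter_set(gen_config)
    return params, truth


@pytest.fixture(scope="session")
def params(gen_params):
    return gen_params[0]


@pytest.fixture(scope="session")
def population(gen_config):
    return generate_population(gen_config)


@pytest.fixture(scope="session")
def grid():
    return scenario_grid()


def scenario_by_label(grid, label):
    return next(s for s in grid if s.label == label)
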