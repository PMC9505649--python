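import numpy as np
import pytest

from franzsim import (
    Discretization,
    ExperimentProtocol,
    make_case_config,
    simulate_case,
)

#: cheap grid for tests that only need qualitative behaviour
COARSE = Discretization(nodes_per_layer=(8, 40, 8), time_step=0.1)


@pytest.fixture(scope="session")
def case1():
    return make_case_config("diclofenac_RT")


@pytest.fixture(scope="session")
def case2():
    return make_case_config("diclofenac_32C")


@pytest.fixture(scope="session")
def case3():
    return make_case_config("caffeine_32C")


@pytest.fixture(scope="session")
def case1_result(case1):
    """Default-resolution forward run of the room-temperature case."""
    return simulate_case(case1, output_times=[0.25, 5.0, 24.0, 47.0])


@pytest.fixture(scope="session")
def case1_coarse(case1):
    times = list(ExperimentProtocol().sampling_times)
    return simulate_case(case1, COARSE, sorted(set(times) | {47.0}))
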