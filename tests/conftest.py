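import numpy as np
import pytest

from hgfdyn.params import reference_parameters
from hgfdyn.simulate import reference_network_packed, simulate, steady_state
from hgfdyn.synth import default_ground_truth


@pytest.fixture(scope="session")
def net_packed():
    return reference_network_packed()


@pytest.fixture(scope="session")
def net(net_packed):
    return net_packed[0]


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def basal_state(net, ref_params):
    return steady_state(net, ref_params)


@pytest.fixture(scope="session")
def sd_trajectory(net_packed, ref_params):
    net, packed = net_packed
    return simulate(net, ref_params, 40.0, np.linspace(0.0, 240.0, 49),
                    packed=packed)
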