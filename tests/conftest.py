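import numpy as np
import pytest

from neurodcm.leadfield import schematic_lead_field
from neurodcm.network import build_default_network


@pytest.fixture(scope="session")
def net():
    return build_default_network()


@pytest.fixture(scope="session")
def pspec(net):
    return net.param_spec()


@pytest.fixture(scope="session")
def lead_field(net):
    return schematic_lead_field(net)


@pytest.fixture(scope="session")
def modes8(lead_field):
    """A fixed orthonormal 21 x 8 mode matrix spanning the lead field."""
    G = lead_field.gain
    U, _, _ = np.linalg.svd(G @ G.T + 0.01 * np.eye(G.shape[0]))
    return U[:, :8]


@pytest.fixture(scope="session")
def forward_model(net, lead_field, modes8):
    from neurodcm.forward import ForwardModel

    return ForwardModel(net, lead_field, modes8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
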