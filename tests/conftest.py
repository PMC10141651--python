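import numpy as np
import pytest

from fusionseg import NetworkConfig, PhantomSpec, generate_case
from fusionseg.backbone import HybridFusionNet


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic 64px four-modality phantom slice."""
    return generate_case(PhantomSpec(image_side=64, seed=11))


@pytest.fixture(scope="session")
def tiny_cfg():
    """A small network configuration usable on 32px inputs."""
    return NetworkConfig(n_modalities=4, n_layers=3, base_filters=4, seed=0)


@pytest.fixture()
def tiny_net(tiny_cfg):
    net = HybridFusionNet(tiny_cfg)
    net.eval()
    return net


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
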