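import numpy as np
import pytest

from mspncalc.channels import load_channel_library, load_densities


@pytest.fixture(scope="session")
def lib():
    return load_channel_library()


@pytest.fixture(scope="session")
def densities():
    return load_densities()


@pytest.fixture(scope="session")
def vgrid():
    return np.linspace(-120.0, 60.0, 361)
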