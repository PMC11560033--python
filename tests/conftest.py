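import numpy as np
import pytest

from gpcrmech.structure import BWScheme
from gpcrmech.synthdata import GeneratorSpec, toy_receptor


@pytest.fixture(scope="session")
def scheme() -> BWScheme:
    return BWScheme()


@pytest.fixture(scope="session")
def default_spec() -> GeneratorSpec:
    return GeneratorSpec()


@pytest.fixture(scope="session")
def receptor_frame(default_spec):
    return toy_receptor(default_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
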