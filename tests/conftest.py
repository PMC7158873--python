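import numpy as np
import pytest

from optirad.phantom import PhantomSpec, make_tract_phantom
from optirad.protocol import default_protocol


@pytest.fixture(scope="session")
def two_shell_protocol():
    """The default two-shell acquisition (b=1000/2200, 60 dirs each, 13 b0)."""
    return default_protocol()


@pytest.fixture(scope="session")
def phantom():
    """A deterministic tract phantom shared across geometry tests."""
    spec = PhantomSpec(seed=1)
    streamlines, parcellation, resection = make_tract_phantom(spec)
    return {
        "spec": spec,
        "streamlines": streamlines,
        "parcellation": parcellation,
        "resection": resection,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
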