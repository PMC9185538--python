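import numpy as np
import pytest

from xrayenhance.phantoms import standard_suite


@pytest.fixture(scope="session")
def suite():
    """The package's fixed synthetic fixture set (built once per session)."""
    return standard_suite()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
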