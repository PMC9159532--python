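import numpy as np
import pytest

from gjmorph.fixtures import CONTROL_LIKE, PKP2CKO_LIKE, build_roi


@pytest.fixture(scope="session")
def control_roi():
    """One rendered control-like ROI (4 plaques) with ground truth."""
    return build_roi(CONTROL_LIKE, seed=11)


@pytest.fixture(scope="session")
def ko_roi():
    """One rendered knockout-like ROI (bulges + orphan runs)."""
    return build_roi(PKP2CKO_LIKE, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
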