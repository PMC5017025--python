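import numpy as np
import pytest

from samtox import LL5Params, StressCapacityDistribution


@pytest.fixture
def symmetric_curve():
    """Symmetric log-logistic: midpoint exactly at e = 10."""
    return LL5Params(b=1.0, c=0.0, d=1.0, e=10.0, f=1.0)


@pytest.fixture
def asymmetric_curve():
    """Asymmetric curve with a sub-unity upper limit."""
    return LL5Params(b=2.0, c=0.0, d=0.9, e=5.0, f=2.0)


@pytest.fixture
def calibrated_dist():
    """Capacity distribution at the calibrated shape p = q = 3.2."""
    return StressCapacityDistribution(3.2, 3.2)


@pytest.fixture
def rng():
    return np.random.default_rng(20160909)
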