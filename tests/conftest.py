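import numpy as np
import pytest

from longdcm import AttributeHierarchy, enumerate_profiles


@pytest.fixture
def linear3():
    return AttributeHierarchy.linear(3)


@pytest.fixture
def divergent3():
    return AttributeHierarchy.divergent(3)


@pytest.fixture
def independent3():
    return AttributeHierarchy.independent(3)


@pytest.fixture
def linear3_space(linear3):
    return enumerate_profiles(linear3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
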