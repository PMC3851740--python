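import pytest

from treevasc import PINE, ASPEN, TreeSpec


@pytest.fixture(scope="session")
def pine_nohw():
    return TreeSpec(params=PINE, L=10.0)


@pytest.fixture(scope="session")
def pine_sw2cm():
    return TreeSpec(params=PINE, L=10.0, r_sw_max=0.02)


@pytest.fixture(scope="session")
def aspen_nohw():
    return TreeSpec(params=ASPEN, L=10.0)
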