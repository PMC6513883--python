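import numpy as np
import pytest

from behavekin import synthetic as syn


@pytest.fixture(scope="session")
def mouse_rig():
    return syn.make_rig("mouse", seed=1)


@pytest.fixture(scope="session")
def human_rig():
    return syn.make_rig("human", seed=2)


@pytest.fixture(scope="session")
def social_class_map():
    return {f"mouse{m}_{p}": (m, p) for m in "AB" for p in ("body", "nose", "head", "tail")}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
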