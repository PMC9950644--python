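import numpy as np
import pytest

from canopysc import synthetic as syn


@pytest.fixture(scope="session")
def default_scene():
    return syn.generate_scene(syn.SceneConfig(seed=42))


@pytest.fixture(scope="session")
def feature_table():
    return syn.generate_feature_table(120, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
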