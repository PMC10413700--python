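import numpy as np
import pytest

from lgesim.params import load_preset

ALL_PRESETS = ("initial", "normal", "scar", "amyloid_midwall", "amyloid_subendo")


@pytest.fixture
def normal():
    return load_preset("normal")


@pytest.fixture
def grid_0_60():
    return np.linspace(0.0, 60.0, 121)
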