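import numpy as np
import pytest

from phrenoscope import synthgen


@pytest.fixture(scope="session")
def e155_left():
    return synthgen.make_nerve_pattern(synthgen.PRESETS["E15.5-left"])


@pytest.fixture(scope="session")
def e155_right():
    return synthgen.make_nerve_pattern(synthgen.PRESETS["E15.5-right"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
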