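import numpy as np
import pytest

import halophen as hp

FEATURES = ["PA", "Sd", "Ht", "dE1", "L", "a", "b", "S", "Hue"]


@pytest.fixture(scope="session")
def trial():
    """Default 96-plant trial table."""
    return hp.trial_table(seed=0)


@pytest.fixture(scope="session")
def rendered_plant():
    """One rendered mid-salinity plant with ground truth (default scale)."""
    params = hp.DEFAULT_GROUPS[("lower", "L-OS")]
    return hp.synthetic.render_plant(params, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
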