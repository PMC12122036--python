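import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lesion_set_64():
    """16 synthetic lesion image/mask pairs at 64x64 (the overfit fixture)."""
    from defifnet.synth import SyntheticSpec, generate_arrays

    spec = SyntheticSpec(mode="lesion", image_size=(64, 64), count=16, seed=123)
    return generate_arrays(spec)
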