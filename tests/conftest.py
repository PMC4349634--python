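import numpy as np
import pytest

from spikesta.corrmodel import MexicanHat


@pytest.fixture
def mexhat_60() -> MexicanHat:
    """Grand-average-like single-spike kernel: 60 nV peak, 0.45 ms wide."""
    return MexicanHat.from_amplitude_width(60.0, 0.45, 0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
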