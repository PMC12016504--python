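import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def uniform_image():
    """Factory for a uniform RGB image of a given gray level."""

    def make(level: int = 128, height: int = 64, width: int = 64) -> np.ndarray:
        return np.full((height, width, 3), level, dtype=np.uint8)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
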