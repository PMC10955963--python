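import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

from scatterct import mask as mask_mod  # noqa: E402


@pytest.fixture(scope="session")
def toy_mask():
    """Small seeded Bernoulli(0.5) mask shared across tests."""
    return mask_mod.generate_mask(64, 64, 100.0, 0.5, seed=7)


@pytest.fixture(scope="session")
def square_system():
    """Full-sampling 16-pixel system with a known ground truth."""
    m = mask_mod.generate_mask(32, 32, 100.0, 0.5, seed=3)
    A = mask_mod.extract_patterns(m, 16, (4, 4), strategy="random-shift", seed=5)
    rng = np.random.default_rng(11)
    x_true = rng.random((4, 4))
    return A, x_true
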