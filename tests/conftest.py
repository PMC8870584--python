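import numpy as np
import pytest

from scalonet.model import CnnSpec, ConvBlock


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_tiles():
    """Trivially separable 128x128 tiles: dark class-0, bright class-1."""
    r = np.random.default_rng(7)
    n = 60
    imgs = np.concatenate(
        [
            np.clip(r.normal(0.2, 0.05, (n, 128, 128)), 0, 1),
            np.clip(r.normal(0.8, 0.05, (n, 128, 128)), 0, 1),
        ]
    )
    labels = np.r_[np.zeros(n, int), np.ones(n, int)]
    return imgs, labels


@pytest.fixture(scope="session")
def mini_spec():
    """A miniature architecture (16x16 input, one block) for gradient math."""
    return CnnSpec(
        input_size=16,
        blocks=(ConvBlock(3, 2, 1),),
        head=(4,),
    )
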