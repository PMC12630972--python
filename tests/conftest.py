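import numpy as np
import pytest

from lesionseg import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest stride-4 network that still exercises every module."""
    return ModelConfig(encoder_filters=(4, 8), bottleneck_filters=16,
                       input_size=32, dropout_rate=0.0)


@pytest.fixture
def tiny_images(rng):
    return rng.random((2, 32, 32, 3)).astype(np.float32)


@pytest.fixture
def tiny_masks(rng):
    masks = np.zeros((2, 32, 32), dtype=np.uint8)
    masks[:, 8:24, 10:22] = 1
    return masks
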