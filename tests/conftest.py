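import numpy as np
import pytest

from msfanet.config import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A small, cheap, but structurally complete architecture."""
    return ModelConfig(rates=(1, 2, 3, 4, 5), branch_channels=4,
                       dropout_rate=0.0, scse_placement="I_and_II", seed=3)


@pytest.fixture
def tiny_batch(rng):
    x = rng.normal(size=(2, 8, 8, 3)).astype(np.float32)
    y = (rng.random((2, 8, 8, 1)) < 0.4).astype(np.uint8)
    return x, y


@pytest.fixture(scope="session")
def small_training_set():
    """40 synthetic 32x32 pairs, channel-standardized, for quick training."""
    from msfanet.synth import generate_arrays
    imgs, masks, _ = generate_arrays(40, image_size=(32, 32), seed=11)
    x = imgs.astype(np.float32) / 255.0
    mean = x.mean(axis=(0, 1, 2))
    std = x.std(axis=(0, 1, 2))
    x = (x - mean) / std
    return x, masks[..., None]
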