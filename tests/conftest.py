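import numpy as np
import pytest

from pointspv import synthetic
from pointspv.encoder import EncoderConfig
from pointspv.simulator import SimulatorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 scene (blob class)."""
    return synthetic.generate_scene(0, size=(128, 128), rng_seed=3)


@pytest.fixture(scope="session")
def small_scenes():
    """A dozen 128x128 scenes, both classes."""
    return synthetic.generate_dataset(12, K=2, size=(128, 128), rng_seed=11)


@pytest.fixture(scope="session")
def tiny_encoder_config():
    """Desk-scale encoder geometry: 64 px patches onto an 8x8 grid."""
    return EncoderConfig(patch_size=64, internal_size=64, grid_size=8)


@pytest.fixture(scope="session")
def tiny_sim_config():
    return SimulatorConfig(frame_size=64, grid_size=8)


@pytest.fixture(scope="session")
def tiny_patch_pairs(small_scenes):
    from pointspv.sampling import build_patch_dataset
    return build_patch_dataset(small_scenes, points_per_object=2, split_fraction=0.75,
                               rng=np.random.default_rng(5), patch_size=64)
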