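import numpy as np
import pytest
from hypothesis import settings

from resswin.dataset import SplitSpec, split_manifest
from resswin.residual import ImprovedModelConfig
from resswin.swin import SwinConfig
from resswin.synthgen import SynthConfig, generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

#: reduced backbone used wherever a forward/backward pass is needed at desk
#: scale (full 224^2 passes are reserved for the few tests that need them)
SMALL_CFG = SwinConfig(img_size=56, embed_dim=32, depths=(2, 2), num_heads=(2, 4))
SMALL_IMPROVED = ImprovedModelConfig(backbone=SMALL_CFG)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    return SMALL_CFG


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """75 synthetic 56px images (25/class), split 80/10/10."""
    root = tmp_path_factory.mktemp("synth")
    cfg = SynthConfig(per_class_counts=(25, 25, 25), image_size=56, seed=11)
    manifest = generate_dataset(cfg, root)
    manifest = split_manifest(manifest, SplitSpec(ratios=(0.8, 0.1, 0.1), seed=0))
    return manifest


def random_image(rng, h=32, w=32):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
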