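import numpy as np
import pytest
from dataclasses import replace

from fundusnet.synthetic_fundus import generate_phantom, preset_a


@pytest.fixture(scope="session")
def phantom():
    """One 256-px phantom with known calibers."""
    return generate_phantom(preset_a(image_size=256, seed=11), image_id="01")


@pytest.fixture(scope="session")
def phantom_batch():
    """Six small phantoms for pipeline-level tests."""
    cfg = preset_a(image_size=192)
    seeds = np.random.default_rng(5).integers(2 ** 31, size=6)
    return [generate_phantom(replace(cfg, seed=int(s)), image_id=f"{i+1:02d}")
            for i, s in enumerate(seeds)]
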