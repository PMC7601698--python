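import numpy as np
import pytest

import capgan as cg


@pytest.fixture(scope="session")
def phantoms16():
    """Small batch of 16x16 phantoms shared across tests (uint8, file range)."""
    spec = cg.PhantomSpec(image_size=16, n_shells=3, intensity_levels=(200, 130, 80), seed=42)
    images, manifest = cg.generate_phantoms(64, spec)
    return images, manifest


@pytest.fixture(scope="session")
def lesion_records():
    return cg.generate_lesion_dataset(12, 40, image_size=64, seed=7, separability=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
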