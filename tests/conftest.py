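import numpy as np
import pytest

from chpseg.io_preproc import LabelMask, Volume
from chpseg.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 48-cube phantom pair, shared across tests (read-only)."""
    params = PhantomParams(shape=(48, 48, 48), target_volume_fraction=0.004,
                           seed=7)
    return generate_phantom(params)


@pytest.fixture()
def ramp_volume():
    """A 3x4x5 ramp grid with distinct values, 1 mm RAS."""
    g = np.arange(3 * 4 * 5, dtype=np.float32).reshape(3, 4, 5)
    return Volume.from_spacing(g)


@pytest.fixture()
def random_mask_pair():
    rng = np.random.default_rng(42)
    x = LabelMask((rng.random((8, 8, 8)) > 0.6).astype(np.uint8), np.eye(4))
    y = LabelMask((rng.random((8, 8, 8)) > 0.6).astype(np.uint8), np.eye(4))
    return x, y
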