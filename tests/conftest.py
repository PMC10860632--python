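import numpy as np
import pytest

from gliaquant.imaging import VolumeImage
from gliaquant.synthdata import EngulfmentPhantomSpec, gen_engulfment_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default noiseless engulfment phantom plus its ground truth."""
    spec = EngulfmentPhantomSpec(seed=3)
    return gen_engulfment_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(data, voxel_size=(0.5, 0.5, 0.5), names=None):
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 3:
        data = data[None]
    if names is None:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return VolumeImage(data, voxel_size, names)
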