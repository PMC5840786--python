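import numpy as np
import pytest

from conjmap.volume_io import MaskedVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_volume(rng):
    """A 12-cube random volume with 3 mm voxels and a loose ellipsoid mask."""
    shape = (12, 12, 12)
    data = rng.standard_normal(shape)
    grids = np.indices(shape).astype(float)
    center = (np.array(shape) - 1) / 2
    mask = sum(((g - c) / 5.5) ** 2 for g, c in zip(grids, center)) <= 1.0
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return MaskedVolume(data, affine, mask)


@pytest.fixture
def toy_ts(rng):
    """Small 4D series (10^3 x 48) with a full mask; TR = 2 s."""
    shape = (10, 10, 10, 48)
    ts = rng.standard_normal(shape)
    template = MaskedVolume(
        np.zeros(shape[:3]), np.diag([3.0, 3.0, 3.0, 1.0])
    )
    return ts, template
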