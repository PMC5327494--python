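import numpy as np
import pytest

from ironmap.geometry import Disk
from ironmap.phantom import PhantomSpec, TissueCompartment, make_phantom


@pytest.fixture
def disk_phantom():
    """Factory: single-disk phantom with chosen relaxation parameters."""

    def _make(t1=900.0, t2=18.0, t2star=11.0, s0=100.0, shape=(32, 32),
              voxel_size=(0.25, 0.25), radius=2.4, heart_rate=600.0):
        comp = TissueCompartment(
            "liver", s0, max(t1, t2), t2, min(t2star, t2), 0.0,
            Disk((shape[0] * voxel_size[0] / 2, shape[1] * voxel_size[1] / 2), radius),
        )
        spec = PhantomSpec(shape=shape, voxel_size=voxel_size,
                           compartments=(comp,), heart_rate=heart_rate)
        return make_phantom(spec)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
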