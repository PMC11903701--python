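import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from burnmetry import CameraExtrinsics, CameraIntrinsics


def random_extrinsics(seed: int) -> CameraExtrinsics:
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(0.0, 0.5, size=3)
    return CameraExtrinsics(R, t)


@pytest.fixture
def simple_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=300.0, fy=300.0, ox=128.0, oy=96.0)
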