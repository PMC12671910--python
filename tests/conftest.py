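import numpy as np
import pytest
from skimage.morphology import ball as digital_ball

from segcurate import LabeledVolume, SynthConfig, generate_nuclei_timelapse


@pytest.fixture
def cube_volume():
    """A 10x10x10 voxel cube (label 1) on an isotropic 1 um grid."""
    data = np.zeros((14, 14, 14), dtype=int)
    data[2:12, 2:12, 2:12] = 1
    return LabeledVolume(data)


def ball_volume(radius: int, pad: int = 2) -> LabeledVolume:
    b = digital_ball(radius)
    data = np.zeros(tuple(s + 2 * pad for s in b.shape), dtype=int)
    sl = tuple(slice(pad, pad + s) for s in b.shape)
    data[sl][b > 0] = 1
    return LabeledVolume(data)


@pytest.fixture(scope="session")
def nuclei_dataset():
    """Well-separated nuclei field with two touching pairs (seeded)."""
    cfg = SynthConfig(seed=3, n_objects=8, n_touching_pairs=2)
    ds, graph = generate_nuclei_timelapse(cfg)
    return ds, graph, cfg
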