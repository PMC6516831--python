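import numpy as np
import pytest

from nucratio.segmentation import NucleusMask, VoxelGrid
from nucratio.synthetic import SyntheticParams, generate_stack


@pytest.fixture
def small_params():
    """Compact noiseless stack: 4 reporter + 3 reference nuclei."""
    return SyntheticParams(
        stack_shape=(20, 160, 160),
        n_pl=4,
        n_da=3,
        noise_model="none",
        seed=11,
    )


@pytest.fixture
def small_stack(small_params):
    return generate_stack(small_params)


def make_mask(labels, voxel_size=(1.0, 0.3, 0.3), threshold=None):
    """Build a NucleusMask from a hand-written label array."""
    labels = np.asarray(labels, dtype=np.int32)
    counts = {}
    centroids = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        support = labels == lab
        counts[int(lab)] = int(support.sum())
        centroids[int(lab)] = tuple(float(c.mean()) for c in np.nonzero(support))
    return NucleusMask(
        labels=labels,
        counts=counts,
        centroids=centroids,
        threshold_used=threshold,
        voxel_size=voxel_size,
    )


def make_grid(green, red, voxel_size=(1.0, 0.3, 0.3), frame_index=0):
    return VoxelGrid(
        green=np.asarray(green, dtype=float),
        red=np.asarray(red, dtype=float),
        voxel_size=voxel_size,
        frame_index=frame_index,
    )
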