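import math

import numpy as np
import pytest

from rvshape import synthetic_cohort as sc
from rvshape import volume_preprocess as vp


def sphere_mask(radius_mm=10.0, spacing=1.0, dims=None, subject_id="sphere"):
    """Binary ball: voxel centers strictly inside the given radius."""
    if dims is None:
        dims = int(2 * math.ceil(radius_mm / spacing) + 9)
    dims = (dims,) * 3
    half = (np.array(dims) - 1) / 2.0 * spacing
    ax = [np.arange(d) * spacing - h for d, h in zip(dims, half)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    vox = x ** 2 + y ** 2 + z ** 2 < radius_mm ** 2
    return vp.SegmentationMask(vox, np.full(3, spacing), -half, subject_id)


@pytest.fixture(scope="session")
def sphere10():
    return sphere_mask(10.0, 1.0)


@pytest.fixture(scope="session")
def sphere10_dt(sphere10):
    return vp.signed_distance_transform(sphere10)


@pytest.fixture(scope="session")
def base_surface():
    return sc.generate_base_surface(24)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort with masks, modest noise."""
    spec = sc.CohortSpec(
        group_sizes={"healthy": 2, "control": 2, "tr": 2},
        noise_sd=0.5, seed=11,
    )
    return sc.generate_cohort(spec)


@pytest.fixture(scope="session")
def default_gt_cohort():
    """Full 54-subject cohort, ground truth only (no voxelization)."""
    spec = sc.CohortSpec(seed=7)
    return sc.generate_cohort(spec, with_masks=False)
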