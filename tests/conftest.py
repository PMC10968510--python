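import numpy as np
import pytest

from noisematch.core import PROFILES, LesionMask, SUVImage
from noisematch.phantom import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small two-profile cohort on a 32x32 grid, shared across tests."""
    spec = CohortSpec(
        n_subjects=10,
        n_normal=5,
        n_abnormal=5,
        total_lesions=12,
        profiles=("Set1-QClear", "Set1-VPFXS-2min"),
        base_seed=7,
        grid_shape=(64, 64),
        spacing=(2.5, 2.5),
    )
    return spec, generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(voxels, spacing=(2.5, 2.5), **kw):
    return SUVImage(np.asarray(voxels, dtype=np.float32), spacing=spacing, **kw)


def make_mask(labels, spacing=(2.5, 2.5)):
    return LesionMask(np.asarray(labels, dtype=np.int32), spacing=spacing)
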