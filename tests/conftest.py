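import numpy as np
import pytest

import korbias as kb


@pytest.fixture(scope="session")
def rmap():
    return kb.default_residue_map()


@pytest.fixture(scope="session")
def reference():
    return kb.reference_frame()


@pytest.fixture(scope="session")
def align_spec(rmap, reference):
    return kb.AlignmentSpec.from_tm_ranges(rmap, reference)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zero_noise_prescription():
    """Fixed-label trajectory prescription with all metric noise off."""
    labels = (
        [kb.StateLabel.OCCLUDED] * 10
        + [kb.StateLabel.ALTERNATIVE] * 10
        + [kb.StateLabel.CANONICAL] * 10
    )
    return kb.StatePrescription(
        n_frames=30,
        seed=7,
        labels=labels,
        noise_sd={k: 0.0 for k in kb.synth.DEFAULT_NOISE_SD},
    )


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng)
    trans = rng.normal(scale=10.0, size=3)
    return lambda pts: rot.apply(np.atleast_2d(pts)) + trans
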