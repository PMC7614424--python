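import numpy as np
import pytest

from petqc import AnatomyParams, generate_phantom, make_cohort


@pytest.fixture(scope="session")
def default_phantom():
    """Desk-scale brain phantom used across patch and thinning tests."""
    return generate_phantom(seed=1, shape=(64, 64, 48))


@pytest.fixture(scope="session")
def normalized_phantom(default_phantom):
    vox = default_phantom.voxels
    return vox / vox.max()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three patients at three count fractions each, small grid."""
    return make_cohort(3, fractions_per_patient=3, seed=7, shape=(48, 48, 40))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flat_anatomy():
    """Anatomy with equal uptake everywhere and no texture: constant head."""
    return AnatomyParams(
        cortex_uptake=0.8, white_uptake=0.8, ventricle_uptake=0.8, texture_amplitude=0.0
    )
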