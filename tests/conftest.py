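import numpy as np
import pytest

from bbsynth import phantom as ph
from bbsynth.preprocess import StudyPair, extract_brain


@pytest.fixture(scope="session")
def default_phantom():
    """One default 96^3 phantom with truth and rendered pair."""
    spec = ph.PhantomSpec(seed=1)
    truth, gre, bb = ph.generate_pair(spec)
    return spec, truth, gre, bb


@pytest.fixture(scope="session")
def default_pair(default_phantom):
    """Brain-masked registered study pair for the default phantom."""
    _, _, gre, bb = default_phantom
    mask = extract_brain(gre)
    return StudyPair(gre=gre, bb=bb, brain_mask=mask, registered=True)


@pytest.fixture(scope="session")
def small_phantom():
    """A 64^3 phantom for cheaper structural tests."""
    spec = ph.PhantomSpec(grid_shape=(64, 64, 64), n_lesions=4, seed=7,
                          lesion_radius_range_mm=(1.0, 4.0))
    truth, gre, bb = ph.generate_pair(spec)
    return spec, truth, gre, bb


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
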