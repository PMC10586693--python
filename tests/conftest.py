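import numpy as np
import pytest

from markerless.augment import train_augmenter
from markerless.models import demo2d, demo3d
from markerless.muscles import fit_muscle_polynomials
from markerless.rig import generate_augmenter_corpus


@pytest.fixture(scope="session")
def model2d():
    return demo2d()


@pytest.fixture(scope="session")
def model3d():
    return demo3d()


@pytest.fixture(scope="session")
def surrogates2d(model2d):
    return fit_muscle_polynomials(model2d, n_postures=1500, max_order=7, seed=0)


@pytest.fixture(scope="session")
def corpus3d():
    """Rig corpus for augmenter tests (held small; the acceptance suite uses
    the full 50-subject corpus)."""
    return generate_augmenter_corpus(n_subjects=15, duration=2.0, seed=0)


@pytest.fixture(scope="session")
def augmenter3d(corpus3d):
    return train_augmenter(corpus3d, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
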