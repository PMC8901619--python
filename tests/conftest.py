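import numpy as np
import pytest

from octavasc.images import EnFaceAngiogram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_angiogram(pixels, layer="superficial", **kwargs):
    return EnFaceAngiogram(np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0),
                           layer=layer, **kwargs)


@pytest.fixture
def random_image(rng):
    """64x64 image with continuous intensities away from 0/1."""
    return make_angiogram(rng.uniform(0.05, 0.95, (64, 64)))


@pytest.fixture(scope="session")
def study_cohort():
    from octavasc.synthetic import CohortParams, generate_cohort

    return generate_cohort(CohortParams(rng_seed=7))
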