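import numpy as np
import pytest

from hsitissue import CohortConfig, build_model, generate_cohort
from hsitissue.io import AnnotationMask, Hypercube


TINY_COHORT_KW = dict(n_animals=6, image_shape=(48, 48), colon_region_area=60,
                      retro_region_thickness=5, seed=11)


@pytest.fixture(scope="session")
def default_model():
    """One built default-architecture model shared across read-only tests."""
    return build_model(seed=123)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six small, well-separated synthetic animals (fast CV fixture)."""
    return generate_cohort(CohortConfig(**TINY_COHORT_KW))


@pytest.fixture()
def flat_cube():
    """A 12x10 cube whose band b is constant b + 1 (handy for band lookups)."""
    bands = np.arange(500.0, 1000.0, 5.0, dtype=np.float32)
    data = np.ones((12, 10, 100), dtype=np.float32) * (np.arange(100) + 1)
    return Hypercube(data.astype(np.float32), bands, animal_id="flat")


def random_mask(rng, h=12, w=10):
    return AnnotationMask(rng.integers(0, 3, size=(h, w)).astype(np.uint8))
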