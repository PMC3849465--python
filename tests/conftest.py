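import numpy as np
import pytest

from hvsroi import FixtureSpec, RGBImage, build_database, generate_image
from hvsroi.fixtures import generate_test_set, generate_training_set, preset


def rand_image(seed: int, h: int = 64, w: int = 64) -> RGBImage:
    rng = np.random.default_rng(seed)
    return RGBImage(rng.uniform(0.0, 1.0, size=(h, w, 3)))


def rand_plane(seed: int, h: int = 64, w: int = 64) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(h, w))


@pytest.fixture(scope="session")
def mag10_spec():
    return preset("mag10")


@pytest.fixture(scope="session")
def mag10_db(mag10_spec):
    """Texton database trained on one mag10 fixture (seed 7)."""
    _, textons, _ = generate_training_set(mag10_spec, 1, 50, base_seed=7)
    return build_database(textons)


@pytest.fixture(scope="session")
def mag10_test_pairs(mag10_spec):
    """Five seeded mag10 test images with ground-truth masks."""
    return generate_test_set(mag10_spec, 5, base_seed=7)


@pytest.fixture(scope="session")
def default_fixture():
    """One default-spec image+mask pair."""
    return generate_image(FixtureSpec(seed=3))
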