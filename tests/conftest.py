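import numpy as np
import pytest

from tractconc.volumes import BinaryMask, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def identity_affine():
    return np.eye(4)


def random_mask(rng, shape=(8, 8, 8), p=0.3, affine=None):
    data = (rng.random(shape) < p).astype(np.uint8)
    return BinaryMask(data, np.eye(4) if affine is None else affine)


def random_volume(rng, shape=(8, 8, 8), affine=None):
    return Volume(rng.random(shape), np.eye(4) if affine is None else affine)


@pytest.fixture
def small_spec():
    """A phantom spec small enough for fast unit tests."""
    from tractconc.synthetic import PhantomSpec

    return PhantomSpec(
        grid_shape=(48, 48, 48),
        tube_radius=3.0,
        fan_radius=5.0,
        ensemble_t=4,
        responses_per_class=8,
        class_distances={"+M1+": (0.0, 1.5), "-M1+": (4.0, 2.0), "-M1-": (10.0, 3.0)},
        seed=11,
    )
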