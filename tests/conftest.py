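import numpy as np
import pytest

from fibrosynth import (
    PhantomSpec,
    generate_fibrous_volume,
    sample_patches,
)
from fibrosynth.distance_map import double_distance_map


@pytest.fixture(scope="session")
def small_phantom():
    """A 48^3 fibrous phantom shared by the slower integration tests."""
    spec = PhantomSpec(shape=(48, 48, 48), target_porosity=0.61, seed=5)
    return generate_fibrous_volume(spec)


@pytest.fixture(scope="session")
def small_dmap(small_phantom):
    return double_distance_map(small_phantom)


@pytest.fixture(scope="session")
def small_dataset(small_dmap):
    return sample_patches(small_dmap, 40, (16, 16, 16), seed=7)
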