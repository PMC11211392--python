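import numpy as np
import pytest

from shgtex import FiberFieldConfig, IntensityImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_image(rng):
    """A 64x64 8-bit noise tile."""
    return IntensityImage(
        pixels=rng.integers(0, 256, size=(64, 64), dtype=np.uint8),
        bit_depth=8,
        source_id="noise64",
    )


@pytest.fixture
def small_null_config():
    """Tiny fiber-field configuration used for statistical replicates."""
    return FiberFieldConfig(
        image_size=96, n_fibers=20, length_mean=30.0, length_sd=10.0,
        orientation_kappa=1.0,
    )


def make_image(pixels, bit_depth=8, source_id="test"):
    return IntensityImage(
        pixels=np.asarray(pixels), bit_depth=bit_depth, source_id=source_id
    )
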