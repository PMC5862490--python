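import numpy as np
import pytest

from flimphasor import AcquisitionMeta, LifetimeMixture, PixelMask, TCSPCImage


@pytest.fixture
def meta():
    return AcquisitionMeta()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_component_mixture():
    return LifetimeMixture((0.3, 0.8, 2.0, 4.0), (0.12, 0.18, 0.45, 0.25))


@pytest.fixture
def small_image(meta, rng):
    """8x8 random stack with plenty of photons per pixel."""
    counts = rng.poisson(40.0, size=(8, 8, meta.n_bins))
    return TCSPCImage(counts, meta)


@pytest.fixture
def no_vessel_mask():
    return PixelMask(np.zeros((8, 8), dtype=bool), label="vessel")
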