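import numpy as np
import pytest

from pentumor.mlt import Histogram
from pentumor.phantoms import Blob, Ellipse, PhantomSpec


@pytest.fixture
def noiseless_tumor_spec() -> PhantomSpec:
    return PhantomSpec(
        image_size=(64, 64),
        mode_intensities=(40.0, 120.0, 200.0),
        mode_sds=(0.0, 0.0, 0.0),
        organ_ellipse=Ellipse((32.0, 32.0), (20.0, 16.0), 0.3),
        tumor_blob=Blob((32.0, 32.0), 6.0),
        has_tumor=True,
        seed=7,
    )


@pytest.fixture
def noiseless_clean_spec(noiseless_tumor_spec) -> PhantomSpec:
    from dataclasses import replace

    return replace(noiseless_tumor_spec, tumor_blob=None, has_tumor=False)


@pytest.fixture
def uniform_hist() -> Histogram:
    return Histogram(np.array([1, 1, 1, 1]), levels=4)


@pytest.fixture
def two_spike_hist() -> Histogram:
    counts = np.zeros(8, dtype=int)
    counts[1] = 5
    counts[6] = 5
    return Histogram(counts, levels=8)


def random_histogram(rng: np.random.Generator, levels: int = 64) -> Histogram:
    counts = rng.integers(0, 40, size=levels)
    counts[rng.integers(0, levels)] += 50  # guarantee occupancy
    return Histogram(counts, levels=levels)
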