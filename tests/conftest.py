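import numpy as np
import pytest

from mmphasor import datasets


@pytest.fixture
def film_matrix_printed():
    """Bundled film matrix exactly as printed (instrument handedness)."""
    return datasets.reference_film_mueller(handedness="instrument")


@pytest.fixture
def film_matrix():
    """Bundled film matrix in the package's canonical handedness."""
    return datasets.reference_film_mueller()


@pytest.fixture
def air_matrix_printed():
    return datasets.reference_air_mueller(handedness="instrument")


@pytest.fixture
def rng():
    return np.random.default_rng(20240808)
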