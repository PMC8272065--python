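import numpy as np
import pytest

from mrscombine.datamodel import AcquisitionMeta


@pytest.fixture
def meta_small() -> AcquisitionMeta:
    """Reduced geometry used throughout the unit tests (4 coils, 8 averages)."""
    return AcquisitionMeta(
        spectral_bandwidth=2000.0,
        n_points=256,
        n_coils=4,
        n_averages=8,
        transmitter_frequency=128.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210625)


def random_rank1(rng, n_coils, n_points):
    """A noiseless rank-1 coil matrix s m^T with its factors."""
    s = rng.standard_normal(n_coils) + 1j * rng.standard_normal(n_coils)
    m = rng.standard_normal(n_points) + 1j * rng.standard_normal(n_points)
    return s, m, np.outer(s, m)


def corr(a, b):
    """Magnitude of the normalized inner product between two vectors."""
    a, b = np.ravel(a), np.ravel(b)
    return abs(np.vdot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))
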