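import numpy as np
import pytest

from nuqloud import features as F
from nuqloud import synthetic as S

#: seed of the fixed synthetic embryo used across the suite
EMBRYO_SEED = 1


@pytest.fixture(scope="session")
def embryo():
    """Default-condition bimodal embryo (~21k cells)."""
    return S.make_embryo(seed=EMBRYO_SEED)


@pytest.fixture(scope="session")
def embryo_features(embryo):
    return F.compute_features(embryo)


@pytest.fixture(scope="session")
def embryo_z(embryo_features):
    return F.zscore(embryo_features)


@pytest.fixture(scope="session")
def small_embryo():
    """Scaled-down embryo for unit-level pipeline tests (~4k cells)."""
    return S.make_embryo(seed=11, semi_axes=(90.0, 60.0, 60.0))


@pytest.fixture(scope="session")
def small_embryo_features(small_embryo):
    return F.compute_features(small_embryo)


@pytest.fixture(scope="session")
def small_embryo_z(small_embryo_features):
    return F.zscore(small_embryo_features)


@pytest.fixture(scope="session")
def gaussian_blobs():
    """Two well-separated 14-dimensional feature clusters with labels."""
    rng = np.random.default_rng(42)
    n = 1000
    x = np.vstack([rng.normal(3.0, 1.0, (n // 2, 14)),
                   rng.normal(-3.0, 1.0, (n // 2, 14))])
    labels = np.repeat([0, 1], n // 2)
    return x, labels
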