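import numpy as np
import pytest

from connfact.parcellation import Parcellation


@pytest.fixture(scope="session")
def small_parcellation() -> Parcellation:
    """30 regions over the 9 default networks (E = 435)."""
    return Parcellation.default(30)


@pytest.fixture(scope="session")
def tiny_parcellation() -> Parcellation:
    """9 regions, one per network (E = 36)."""
    return Parcellation.default(9)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_corpus() -> np.ndarray:
    """20 documents over 6 words; two groups with disjoint vocabulary."""
    gen = np.random.default_rng(7)
    x = np.zeros((20, 6))
    x[:10, :3] = gen.integers(1, 10, (10, 3))
    x[10:, 3:] = gen.integers(1, 10, (10, 3))
    return x
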