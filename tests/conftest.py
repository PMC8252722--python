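import numpy as np
import pytest

from heteromap import AbundanceDistribution, relative_abundances


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_distribution(rng, max_richness=12, max_count=30):
    """A random valid AbundanceDistribution built from integer counts."""
    k = int(rng.integers(1, max_richness + 1))
    counts = rng.integers(1, max_count, size=k)
    values = rng.choice(np.arange(10 * max_richness), size=k, replace=False)
    sample = np.repeat(np.sort(values), counts)
    return relative_abundances(sample)


def random_sample(rng, max_size=81, alphabet=16):
    """A random scalar window sample (1-D int array)."""
    n = int(rng.integers(1, max_size + 1))
    return rng.integers(0, alphabet, size=n)


@pytest.fixture
def uniform9():
    """The 9-distinct-value distribution (each p = 1/9)."""
    return relative_abundances(np.arange(1, 10))
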