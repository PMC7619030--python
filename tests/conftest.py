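import numpy as np
import pytest

from lexmap.embeddings import EmbeddingStore, SubwordTable
from lexmap.geography import Station


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_store():
    """Three labelled unit-ish vectors in 3-D."""
    store = EmbeddingStore(dim=3)
    store.add("Angel", np.array([1.0, 0.0, 0.0]))
    store.add("Bank", np.array([0.0, 1.0, 0.0]))
    store.add("Oval", np.array([1.0, 1.0, 0.0]))
    return store


@pytest.fixture
def small_table(rng):
    """A small random subword bucket table (dim 4, 97 buckets)."""
    return SubwordTable(buckets=rng.standard_normal((97, 4)), minn=5, maxn=5)


@pytest.fixture
def toy_stations():
    """Three stations of one city at hand-chosen coordinates."""
    return [
        Station(id="T-0", name="Angel", city="Toyville", lat=51.5, lon=0.0),
        Station(id="T-1", name="Bank", city="Toyville", lat=51.6, lon=0.1),
        Station(id="T-2", name="Oval", city="Toyville", lat=51.4, lon=-0.1),
    ]
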