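import numpy as np
import pytest

from rootsoc import io_tables, synth


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic collection at the default study conditions."""
    return synth.generate(synth.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_profiles(default_dataset):
    ds = default_dataset
    return io_tables.profiles_from_frames(ds.sites, ds.horizons, ds.roots)


def random_layer_geometry(rng, depth=200.0, max_pieces=8, min_th=2.0):
    """Random sorted, non-overlapping interval partition of [0, depth)."""
    n = int(rng.integers(1, max_pieces + 1))
    for _ in range(100):
        cuts = np.sort(rng.uniform(min_th, depth - min_th, size=n - 1))
        edges = np.concatenate([[0.0], cuts, [depth]])
        if np.all(np.diff(edges) >= min_th):
            return [(float(edges[i]), float(edges[i + 1])) for i in range(n)]
    edges = np.linspace(0.0, depth, n + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n)]
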