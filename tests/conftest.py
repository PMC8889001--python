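import numpy as np
import pytest

from wfclust import Dataset, PlantedBinarySpec, make_planted_binary


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_planted():
    """Five planted Jaccard clusters, 100 points each (seed-fixed)."""
    spec = PlantedBinarySpec(seed=7)
    codes, labels = make_planted_binary(spec)
    return spec, codes, np.array(labels)


@pytest.fixture
def toy_points():
    return Dataset.from_array(np.array([[0.0, 0.0], [3.0, 4.0], [0.1, 0.2]]))
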