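import logging

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from soilbiome.clustering import ClusterSolution
from soilbiome.synthetic import ScenarioConfig, generate_scenario

logging.getLogger("soilbiome").setLevel(logging.ERROR)


@pytest.fixture
def tight_pairs_dist():
    """Two well-separated tight pairs: within-distance 0.01, between 0.99."""
    d = np.full((4, 4), 0.99)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.01
    d[2, 3] = d[3, 2] = 0.01
    return DistanceMatrix(d, ids=["a", "b", "c", "d"])


@pytest.fixture
def tight_pairs_solution():
    return ClusterSolution(k=2, labels=pd.Series([1, 1, 2, 2], index=["a", "b", "c", "d"]))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest scenario reused by read-only tests."""
    config = ScenarioConfig(
        n_sites=40,
        n_otus=80,
        n_responsive_otus=20,
        n_replicates=3,
        depth_mean=600,
        effect_size_chem=2.0,
        effect_size_landuse=2.0,
        seed=11,
    )
    return generate_scenario(config)


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """A random symmetric dissimilarity matrix (not necessarily Euclidean)."""
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
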