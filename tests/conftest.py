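import numpy as np
import pandas as pd
import pytest

from seedpref.distances import DistanceMatrix


def make_dm(values, labels=None, block_name="block") -> DistanceMatrix:
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(tuple(labels), values, block_name=block_name)


def random_distance_matrix(rng: np.random.Generator, n: int,
                           block_name: str = "block") -> DistanceMatrix:
    """Random symmetric zero-diagonal matrix with uniform off-diagonals."""
    d = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
    from scipy.spatial.distance import squareform
    return make_dm(squareform(d), block_name=block_name)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default synthetic study (28 seeds, 37 predators)."""
    from seedpref.synthetic import SyntheticScenario, generate_dataset
    return generate_dataset(SyntheticScenario(seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_consumption():
    from seedpref.traits import ConsumptionTable
    data = pd.DataFrame(
        {"pred_a": [10.0, 5.0, 0.0], "pred_b": [7.0, 7.0, 7.0],
         "pred_c": [0.0, 0.0, 0.0]},
        index=pd.Index(["sp1", "sp2", "sp3"], name="species_id"))
    return ConsumptionTable(data, standardized=False)
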