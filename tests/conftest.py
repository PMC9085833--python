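import numpy as np
import pytest

from batconnectome.distances import DistanceMatrix


@pytest.fixture
def asym5() -> DistanceMatrix:
    """Small asymmetric 5-gene matrix with hand-set distances."""
    rng = np.random.default_rng(42)
    v = rng.uniform(1.0, 10.0, size=(5, 5))
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(("A", "B", "C", "D", "E"), v)


@pytest.fixture
def sym4() -> DistanceMatrix:
    v = np.array(
        [
            [0.0, 1.0, 4.0, 5.0],
            [1.0, 0.0, 3.5, 4.5],
            [4.0, 3.5, 0.0, 2.0],
            [5.0, 4.5, 2.0, 0.0],
        ]
    )
    return DistanceMatrix(("a", "b", "c", "d"), v)
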