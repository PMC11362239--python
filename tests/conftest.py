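import numpy as np
import pytest

from seqnum.dataset_builder import build_dataset, default_grid, subsample_balanced
from seqnum.sequence_gen import GenerationConstraints


@pytest.fixture(scope="session")
def dataset500():
    """Default 500-pair dataset, shared across tests (read-only)."""
    return build_dataset(500, seed=7)


@pytest.fixture(scope="session")
def subsample120(dataset500):
    return subsample_balanced(dataset500, 120, np.random.default_rng(11))


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def constraints():
    return GenerationConstraints()


def random_cardinal_points(rng, n_points):
    """Random valid cardinal points over a broad realistic range."""
    pts = []
    from seqnum.feature_space import CardinalPoint

    for _ in range(n_points):
        n = int(rng.integers(2, 40))
        dur = float(np.exp(rng.uniform(np.log(10), np.log(2000))))
        tmsp = dur * float(np.exp(rng.uniform(0, np.log(50))))
        pts.append(CardinalPoint(n=n, dur=dur, tmsp=tmsp))
    return pts
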