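import numpy as np
import pytest

from tnulls import TemporalGraph, alternating_triplet_fixture, star_fixture


def random_temporal_graph(n_nodes, n_steps, p, seed):
    """Erdős–Rényi-per-snapshot temporal graph, for oracles and property checks."""
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n_steps, n_nodes, n_nodes)) < p, 1)
    tensor = (upper | upper.transpose(0, 2, 1)).astype(np.uint8)
    return TemporalGraph(tensor, validate=False)


@pytest.fixture
def star4():
    return star_fixture(4)


@pytest.fixture
def alt4():
    return alternating_triplet_fixture(4)
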