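import numpy as np
import pytest

from axonmatch.skeletons import Skeleton


def random_tree(rng, n_nodes=50, scale=10_000.0, tree_id=1):
    """Random tree: node k>0 attaches to a random earlier node."""
    positions = rng.uniform(0, scale, size=(n_nodes, 3))
    edges = [(int(rng.integers(0, k)), k) for k in range(1, n_nodes)]
    node_ids = np.arange(n_nodes)
    return Skeleton(tree_id, node_ids, positions,
                    np.array(edges, dtype=np.int64).reshape(-1, 2))


def straight_axon(start, direction, length_nm, spacing_nm=500.0, tree_id=1):
    """Straight polyline from start along a unit direction."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n = int(np.floor(length_nm / spacing_nm)) + 1
    pts = np.asarray(start, dtype=float) + \
        np.arange(n)[:, None] * spacing_nm * direction
    edges = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    return Skeleton(tree_id, np.arange(n), pts, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_tree():
    return random_tree


@pytest.fixture
def make_straight_axon():
    return straight_axon
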