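import numpy as np
import pytest

from osteopem import PhyloTree, SimulationConfig, simulate_dataset, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


def random_tree(n_tips: int, rng: np.random.Generator) -> PhyloTree:
    """Random Yule time tree used across property tests."""
    return simulate_tree(n_tips, birth_rate=1.0, rng=rng)


def shared_path_matrix_oracle(tree: PhyloTree) -> np.ndarray:
    """Brute-force BM covariance: shared root-to-tip path length per tip pair.

    Walks each root-to-tip path independently of the influence-matrix code.
    """
    tips = tree.tips()
    paths = []
    for tip in tips:
        path = []
        node = tip
        while node.parent is not None:
            path.append((id(node), node.length))
            node = node.parent
        paths.append(dict(path))
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = sum(l for e, l in paths[i].items() if e in paths[j])
    return C


@pytest.fixture
def small_dataset():
    """A 12-tip synthetic dataset with one withheld target tip."""
    config = SimulationConfig(n_tips=12, seed=99)
    return simulate_dataset(config, n_targets=1)
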