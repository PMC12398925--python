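import numpy as np
import pytest

import phyloquartet as pq

# Canonical study conditions used across the suite: a 13-taxon reference
# tree with branch lengths and the default three-segment simulated
# alignment along it.
STUDY_TREE_SEED = 7
STUDY_ALN_SEED = 3

QUARTET_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture(scope="session")
def study_tree() -> pq.ReferenceTree:
    return pq.random_binary_tree(13, seed=STUDY_TREE_SEED)


@pytest.fixture(scope="session")
def study_alignment(study_tree):
    return pq.simulate_alignment(study_tree, seed=STUDY_ALN_SEED)


@pytest.fixture(scope="session")
def quartet_tree() -> pq.ReferenceTree:
    return pq.parse_newick(QUARTET_NEWICK)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_symmetric_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random nonnegative symmetric matrix with zero diagonal."""
    A = rng.uniform(0.0, 5.0, size=(n, n))
    D = (A + A.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D
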