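import numpy as np
import pytest

from brushnet import BehaviorVector, CohortSpec, FriendshipMatrix, generate_cohort


def random_digraph(rng: np.random.Generator, n: int, max_out: int = 5) -> FriendshipMatrix:
    """Random directed graph with out-degree <= max_out (no self-loops)."""
    adj = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        k = int(rng.integers(0, min(max_out, n - 1) + 1))
        if k:
            targets = rng.choice(np.delete(np.arange(n), i), size=k, replace=False)
            adj[i, targets] = 1
    return FriendshipMatrix(adj)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def chain() -> FriendshipMatrix:
    """a -> b -> c -> d path."""
    return FriendshipMatrix.from_edges([(0, 1), (1, 2), (2, 3)], 4)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across read-only tests."""
    state, ses = generate_cohort(CohortSpec(seed=42))
    return state, ses


@pytest.fixture
def scores4() -> BehaviorVector:
    return BehaviorVector([1, 2, 3, 4])
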